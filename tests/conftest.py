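import numpy as np
import pytest

from polstripe import RegionOfInterest, SceneConfig, StripeClassSpec, render_series

PROTOCOL = np.array([-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0])


@pytest.fixture(scope="session")
def protocol_angles():
    return PROTOCOL.copy()


@pytest.fixture
def clean_config():
    """Noise-free default scene: distinct class degrees, shared phase."""
    return SceneConfig(noise_sd=0.0, seed=7)


@pytest.fixture
def clean_scene(clean_config):
    return render_series(clean_config)


@pytest.fixture
def noisy_config():
    return SceneConfig(noise_sd=3.0, seed=11)


@pytest.fixture
def center_roi():
    """ROI inside the default 128×128 scene's striped target."""
    return RegionOfInterest(label="flank", rect=(30, 30, 60, 60))


def make_spec(b=100.0, d=0.2, phase=-45.0):
    return StripeClassSpec(mean_luminance=b, degree=d, phase_deg=phase)
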
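"""Synthetic striped scenes with known polarization ground truth.

Forward model
-------------
Each pixel belongs to one of three classes — black stripe, white stripe
or vegetated background — and its expected luminance as the polarizer
rotates follows the same 180°-period sinusoid that the analysis fits:

    L(θ) = b · (1 + d · sin(2·(θ + φ)))

with baseline luminance ``b``, degree of linear polarization ``d`` and
polarization phase ``φ`` (filter-angle degrees; φ = −45° means
predominantly horizontally polarized light, which peaks with the filter
at ±90°). Additive Gaussian sensor noise, clipped at zero, is applied
after the sinusoid. Because the generator *is* the fit model, every
downstream stage is testable by exact parameter recovery in the
noise-free limit.

Stripes are hard-edged parallel bands (optional 1-px linear feathering)
on a rectangular target placed over a uniform background field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._toml import dumps as toml_dumps
from .series_io import PROTOCOL_ANGLES_DEG, PolarizerSeries, save_series


def class_luminance(
    angles_deg: np.ndarray | Sequence[float],
    mean_luminance: float,
    degree: float,
    phase_deg: float,
) -> np.ndarray:
    """Expected luminance of one class at the given filter angles."""
    th = np.radians(np.asarray(angles_deg, dtype=np.float64) + phase_deg)
    return mean_luminance * (1.0 + degree * np.sin(2.0 * th))


@dataclass(frozen=True)
class StripeClassSpec:
    """Ground-truth polarization parameters of one scene class.

    ``mean_luminance`` is the sinusoid baseline b (arbitrary linear
    units), ``degree`` the degree of linear polarization d in [0, 1],
    ``phase_deg`` the polarization phase φ in [−90, +90) filter-angle
    degrees.
    """

    mean_luminance: float
    degree: float
    phase_deg: float = -45.0

    def __post_init__(self) -> None:
        if self.mean_luminance <= 0:
            raise ValueError("mean_luminance must be positive")
        if not 0.0 <= self.degree <= 1.0:
            raise ValueError("degree must lie in [0, 1]")
        if not -90.0 <= self.phase_deg < 90.0:
            raise ValueError("phase_deg must lie in [−90, +90)")

    def luminance(self, angles_deg) -> np.ndarray:
        return class_luminance(angles_deg, self.mean_luminance, self.degree, self.phase_deg)


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of a synthetic polarizer series.

    The default filter-angle list is the field protocol: −90° to +90°
    in 30° steps with replicate endpoints. ``target_rect`` is the
    (row0, col0, height, width) of the striped target; by default a
    centred rectangle covering 70% of each dimension. ``noise_sd`` is
    the additive Gaussian sensor-noise s.d. in luminance units.
    """

    image_height: int = 128
    image_width: int = 128
    stripe_period: int = 16
    stripe_orientation_deg: float = 0.0
    black_spec: StripeClassSpec = field(
        default_factory=lambda: StripeClassSpec(mean_luminance=60.0, degree=0.25, phase_deg=-45.0)
    )
    white_spec: StripeClassSpec = field(
        default_factory=lambda: StripeClassSpec(mean_luminance=160.0, degree=0.15, phase_deg=-45.0)
    )
    background_spec: StripeClassSpec = field(
        default_factory=lambda: StripeClassSpec(mean_luminance=110.0, degree=0.10, phase_deg=-45.0)
    )
    filter_angles_deg: tuple[float, ...] = PROTOCOL_ANGLES_DEG
    noise_sd: float = 0.0
    pixels_per_degree: float = 89.5
    capture_distance_m: float = 50.0
    target_rect: tuple[int, int, int, int] | None = None
    feather_px: float = 0.0
    texture_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 4 or self.image_width < 4:
            raise ValueError("image must be at least 4×4 pixels")
        if self.stripe_period < 2:
            raise ValueError("stripe_period must be ≥ 2 px")
        if self.stripe_period > min(self.image_height, self.image_width):
            raise ValueError(
                f"degenerate geometry: stripe_period {self.stripe_period} exceeds "
                f"image extent {min(self.image_height, self.image_width)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.feather_px < 0:
            raise ValueError("feather_px must be ≥ 0")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be ≥ 0")
        if len(self.filter_angles_deg) < 4:
            raise ValueError("need at least 4 filter angles to fit 3 parameters")
        if self.filter_angles_deg[0] != -90.0 or self.filter_angles_deg[-1] != 90.0:
            raise ValueError("filter angle list must start at −90° and end at +90° (replicate endpoints)")
        if self.pixels_per_degree <= 0 or self.capture_distance_m <= 0:
            raise ValueError("calibration values must be positive")

    def resolved_target_rect(self) -> tuple[int, int, int, int]:
        if self.target_rect is not None:
            r0, c0, h, w = self.target_rect
            if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > self.image_height or c0 + w > self.image_width:
                raise ValueError(f"target_rect {self.target_rect} outside {self.image_height}×{self.image_width} frame")
            return (r0, c0, h, w)
        mh = int(round(0.15 * self.image_height))
        mw = int(round(0.15 * self.image_width))
        return (mh, mw, self.image_height - 2 * mh, self.image_width - 2 * mw)


@dataclass
class SceneGroundTruth:
    """What the generator knows: per-class masks and parameters."""

    config: SceneConfig
    masks: dict[str, np.ndarray]  # 'black' | 'white' | 'background' -> bool array
    specs: dict[str, StripeClassSpec]
    white_weight: np.ndarray  # continuous white-stripe mixing weight in [0,1]
    offsets: list[tuple[int, int]] | None = None  # per-image (drow, dcol), if jittered

    @property
    def stripe_mask(self) -> np.ndarray:
        """Boolean mask over the target: True = white stripe."""
        return self.masks["white"]


def _white_weight(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Continuous white-stripe weight map and target mask."""
    rows, cols = np.mgrid[0 : config.image_height, 0 : config.image_width]
    a = np.radians(config.stripe_orientation_deg)
    # band coordinate: projection onto the stripe normal; orientation 0
    # gives vertical stripes alternating along the column axis
    u = cols * np.cos(a) + rows * np.sin(a)
    s = np.mod(u / config.stripe_period, 1.0)
    if config.feather_px > 0:
        # signed distance (px) to the nearest black/white boundary,
        # positive inside the white half-period s ∈ [0, 0.5)
        dist = np.minimum(np.mod(s, 0.5), 0.5 - np.mod(s, 0.5)) * config.stripe_period
        signed = np.where(s < 0.5, dist, -dist)
        weight = np.clip(0.5 + signed / config.feather_px, 0.0, 1.0)
    else:
        weight = (s < 0.5).astype(np.float64)
    r0, c0, h, w = config.resolved_target_rect()
    target = np.zeros((config.image_height, config.image_width), dtype=bool)
    target[r0 : r0 + h, c0 : c0 + w] = True
    return weight, target


def render_series(config: SceneConfig) -> tuple[PolarizerSeries, SceneGroundTruth]:
    """Render a polarizer series of a striped target on background.

    Returns the series and the ground truth (class masks, per-class
    parameters, continuous mixing weights). Deterministic: the same
    config (including seed) yields bit-identical pixels.
    """
    weight, target = _white_weight(config)
    angles = np.asarray(config.filter_angles_deg)
    rng = np.random.default_rng(config.seed)

    lb = config.black_spec.luminance(angles)
    lw = config.white_spec.luminance(angles)
    lg = config.background_spec.luminance(angles)

    # static multiplicative albedo texture (pelage/vegetation graininess),
    # identical across filter angles: it rescales b per pixel but leaves
    # per-pixel d and φ untouched, and gives ROI tracking real structure
    if config.texture_sd > 0:
        texture = np.exp(rng.normal(0.0, config.texture_sd, size=(config.image_height, config.image_width)))
    else:
        texture = 1.0

    images = []
    for k in range(len(angles)):
        fg = weight * lw[k] + (1.0 - weight) * lb[k]
        im = np.where(target, fg, lg[k]) * texture
        if config.noise_sd > 0:
            im = im + rng.normal(0.0, config.noise_sd, size=im.shape)
            im = np.clip(im, 0.0, None)
        images.append(im)

    masks = {
        "white": target & (weight >= 0.5),
        "black": target & (weight < 0.5),
        "background": ~target,
    }
    series = PolarizerSeries(
        images=images,
        filter_angles_deg=list(angles),
        pixels_per_degree=config.pixels_per_degree,
        capture_distance_m=config.capture_distance_m,
        metadata={"synthetic": True, "seed": config.seed},
    )
    truth = SceneGroundTruth(
        config=config,
        masks=masks,
        specs={
            "black": config.black_spec,
            "white": config.white_spec,
            "background": config.background_spec,
        },
        white_weight=weight,
    )
    return series, truth


def render_motion_jitter(
    series: PolarizerSeries, offsets: Sequence[tuple[int, int]]
) -> PolarizerSeries:
    """Translate each image by an integer (drow, dcol) offset.

    Emulates subject movement between exposures so ROI tracking can be
    exercised against known displacements. Offsets are applied with
    wrap-around (periodic scene continuation); offsets as large as the
    frame are rejected.
    """
    if len(offsets) != series.n_images:
        raise ValueError(f"need one offset per image ({series.n_images}), got {len(offsets)}")
    h, w = series.shape
    images = []
    for (dr, dc), im in zip(offsets, series.images):
        dr, dc = int(dr), int(dc)
        if abs(dr) >= h or abs(dc) >= w:
            raise ValueError(f"offset ({dr}, {dc}) exceeds image bounds {h}×{w}")
        images.append(np.roll(im, (dr, dc), axis=(0, 1)))
    out = PolarizerSeries(
        images=images,
        filter_angles_deg=list(series.filter_angles_deg),
        pixels_per_degree=series.pixels_per_degree,
        capture_distance_m=series.capture_distance_m,
        exposure_locked=series.exposure_locked,
        metadata=dict(series.metadata),
    )
    out.metadata["true_offsets"] = [(int(r), int(c)) for r, c in offsets]
    return out


def write_scene(
    series: PolarizerSeries,
    truth: SceneGroundTruth,
    directory,
    prefix: str = "scene",
) -> dict[str, object]:
    """Write the series as 16-bit TIFFs plus a TOML ground-truth sidecar.

    Returns ``{"tiffs": [...], "sidecar": path}``.
    """
    import os

    paths = save_series(series, directory, prefix=prefix)
    cfg = truth.config
    sidecar = {
        "filter_angles_deg": list(cfg.filter_angles_deg),
        "pixels_per_degree": cfg.pixels_per_degree,
        "capture_distance_m": cfg.capture_distance_m,
        "noise_sd": cfg.noise_sd,
        "stripe_period": cfg.stripe_period,
        "stripe_orientation_deg": cfg.stripe_orientation_deg,
        "seed": cfg.seed,
        "target_rect": list(cfg.resolved_target_rect()),
        "files": [os.path.basename(p) for p in paths],
    }
    for name, spec in truth.specs.items():
        sidecar[name] = {
            "mean_luminance": spec.mean_luminance,
            "degree": spec.degree,
            "phase_deg": spec.phase_deg,
        }
    sidecar_path = os.path.join(os.fspath(directory), f"{prefix}_truth.toml")
    with open(sidecar_path, "w") as fh:
        fh.write(toml_dumps(sidecar))
    return {"tiffs": paths, "sidecar": sidecar_path}
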
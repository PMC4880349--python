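"""Compound-eye acuity model: how a fly sees the scene from a distance.

Host-seeking biting flies (tabanids, glossinids) have coarse compound
eyes with an angular acuity near 1° — orders of magnitude below the
camera's. Their view from distance D is emulated by convolving each
luminance image with a Gaussian whose angular width is the acceptance
function of the eye: at the capture distance the 1° kernel spans
``pixels_per_degree`` pixels, and the same angular width scales
linearly with D, so moving the simulated observer further away widens
the blur in image pixels proportionally. Stripe segmentation masks
from the *unblurred* images are reused verbatim at every distance, and
the filter is applied to the full frame before any ROI is cut, to
avoid boundary artifacts.

The sweep produces the central visibility result: Michelson stripe
contrast and the black/white polarization-degree difference both wash
out within tens of metres, while the pooled polarization signal of the
whole coat persists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fitting import RoiSegmentation, fit_sinusoid, michelson
from .series_io import PolarizerSeries

#: FWHM of a unit-σ Gaussian: 2·sqrt(2·ln 2).
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_DISTANCES_M = (1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0)


@dataclass(frozen=True)
class AcuityConfig:
    """Observer acuity and distance grid.

    ``acuity_deg`` is the angular width of the Gaussian acceptance
    function (default 1°, blowfly-like); ``width_convention`` states
    whether that width is the kernel's FWHM (default, the standard
    parameterization of ommatidial acceptance functions) or its σ.
    ``distance_grid_m`` is ascending observer distances out to 50 m.
    """

    pixels_per_degree: float
    capture_distance_m: float
    acuity_deg: float = 1.0
    width_convention: str = "fwhm"
    distance_grid_m: tuple[float, ...] = DEFAULT_DISTANCES_M

    def __post_init__(self) -> None:
        if self.acuity_deg <= 0:
            raise ValueError("acuity_deg must be positive")
        if self.width_convention not in ("fwhm", "sigma"):
            raise ValueError("width_convention must be 'fwhm' or 'sigma'")
        if self.pixels_per_degree <= 0 or self.capture_distance_m <= 0:
            raise ValueError("calibration values must be positive")
        grid = tuple(float(d) for d in self.distance_grid_m)
        if len(grid) == 0:
            raise ValueError("distance grid must not be empty")
        if any(d <= 0 for d in grid):
            raise ValueError("distances must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("distance grid must be strictly ascending")
        object.__setattr__(self, "distance_grid_m", grid)


def blur_sigma_pixels(config: AcuityConfig, distance_m: float) -> float:
    """Gaussian σ in capture-image pixels for an observer at ``distance_m``.

    The acceptance function subtends ``acuity_deg`` at the observer;
    projected onto the capture image this is
    width_px = acuity_deg × pixels_per_degree × distance / capture_distance,
    converted to σ by the width convention (σ = width/2.3548 for FWHM).
    σ scales linearly with distance and vanishes as distance → 0.
    """
    if distance_m < 0:
        raise ValueError("distance must be ≥ 0")
    width_px = config.acuity_deg * config.pixels_per_degree * (distance_m / config.capture_distance_m)
    if config.width_convention == "fwhm":
        return float(width_px / FWHM_PER_SIGMA)
    return float(width_px)


def blur_image(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Full-frame 2-D Gaussian blur; σ = 0 is the identity.

    Reflective boundary handling conserves total luminance and avoids
    dark-edge artifacts near the frame borders.
    """
    if sigma_px < 0:
        raise ValueError("sigma must be ≥ 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma_px == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma_px, mode="reflect")


@dataclass
class VisibilityCurve:
    """Per-ROI visibility of stripes and polarization vs. distance.

    For each distance: the degree of polarization of each stripe class
    (original masks on blurred images), the mask-free pooled-ROI
    degree, and the mean Michelson stripe contrast. ``converged_d`` is
    the pooled degree at the largest distance — the polarization signal
    a distant low-acuity observer still receives after the stripes have
    blurred together.
    """

    roi_label: str
    distances_m: np.ndarray
    d_black: np.ndarray
    d_white: np.ndarray
    d_pooled: np.ndarray
    contrast: np.ndarray
    converged_d: float

    def to_frame(self):
        """Tidy (distance_m, metric, value) table for plotting/export."""
        import pandas as pd

        rows = []
        for name, vals in (
            ("d_black", self.d_black),
            ("d_white", self.d_white),
            ("d_pooled", self.d_pooled),
            ("michelson_contrast", self.contrast),
        ):
            for dist, v in zip(self.distances_m, vals):
                rows.append({"roi_label": self.roi_label, "distance_m": dist, "metric": name, "value": v})
        return pd.DataFrame(rows)


def visibility_sweep(
    series: PolarizerSeries,
    roi_seg: RoiSegmentation,
    config: AcuityConfig,
) -> VisibilityCurve:
    """Recompute polarization and stripe contrast at simulated distances.

    For every distance in the grid, each filter-angle image is blurred
    full-frame with the distance-scaled acceptance function; class mean
    luminances are re-extracted with the *original* (unblurred-image)
    stripe masks and refitted, giving d per class; the mask-free pooled
    ROI mean is fitted likewise; Michelson contrast is averaged over
    filter settings.
    """
    if roi_seg.excluded:
        raise ValueError(f"ROI {roi_seg.roi.label!r} was excluded: {roi_seg.reason}")
    roi = roi_seg.roi
    angles = np.asarray(series.filter_angles_deg)
    distances = np.asarray(config.distance_grid_m)

    d_black = np.empty_like(distances)
    d_white = np.empty_like(distances)
    d_pooled = np.empty_like(distances)
    contrast = np.empty_like(distances)

    for j, dist in enumerate(distances):
        sigma = blur_sigma_pixels(config, dist)
        lw, lb, lpool, per_image_contrast = [], [], [], []
        for i, im in enumerate(series.images):
            blurred = blur_image(im, sigma)
            window = roi.window(blurred, i)
            mask = roi_seg.per_image[i].mask
            mw, mb = float(window[mask].mean()), float(window[~mask].mean())
            lw.append(mw)
            lb.append(mb)
            lpool.append(float(window.mean()))
            per_image_contrast.append(michelson(mw, mb))
        d_black[j] = fit_sinusoid(angles, np.asarray(lb)).degree_d
        d_white[j] = fit_sinusoid(angles, np.asarray(lw)).degree_d
        d_pooled[j] = fit_sinusoid(angles, np.asarray(lpool)).degree_d
        contrast[j] = float(np.mean(per_image_contrast))

    return VisibilityCurve(
        roi_label=roi.label,
        distances_m=distances,
        d_black=d_black,
        d_white=d_white,
        d_pooled=d_pooled,
        contrast=contrast,
        converged_d=float(d_pooled[-1]),
    )
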
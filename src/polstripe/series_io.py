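"""Polarizer image series: container, TIFF I/O, luminance conversion.

A *polarizer series* is a set of co-registered photographs of one scene
taken in quick succession through a linear polarizing filter rotated to
a known angle for each exposure (protocol: 7 images from −90° to +90°
in 30° steps, so the −90°/+90° endpoints are replicate observations).
Pixel values are linear luminance up to an unknown per-series scale
factor, which is why exposure must be locked within a series: the
polarization analysis relies on luminance *ratios* across filter
angles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import tifffile

#: Rec. 601 luma coefficients, as used by MATLAB's ``rgb2gray``.
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

#: The rotating-filter protocol: 180° sweep in 30° steps, replicate endpoints.
PROTOCOL_ANGLES_DEG = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)


@dataclass
class PolarizerSeries:
    """Ordered stack of luminance images, one per polarizer angle.

    Parameters
    ----------
    images
        2-D float arrays of linear luminance (arbitrary common scale),
        all the same shape, in the same order as ``filter_angles_deg``.
    filter_angles_deg
        Polarizer filter angle of each image, degrees in [−90, +90];
        ±90° means the minimum-transmission axis is vertical.
    pixels_per_degree
        Angular resolution of the capture (px per degree of visual
        angle at the subject).
    capture_distance_m
        Camera-to-subject distance in metres.
    exposure_locked
        Whether exposure was held fixed across the series. Polarimetric
        quantities are luminance ratios across images and are invalid
        otherwise.
    metadata
        Free-form capture notes (sun azimuth/elevation, illumination
        flags, body-axis angle, ...).
    """

    images: list[np.ndarray]
    filter_angles_deg: Sequence[float]
    pixels_per_degree: float
    capture_distance_m: float
    exposure_locked: bool = True
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = [np.asarray(im, dtype=np.float64) for im in self.images]
        self.filter_angles_deg = [float(a) for a in self.filter_angles_deg]
        if len(self.images) == 0:
            raise ValueError("series must contain at least one image")
        if len(self.images) != len(self.filter_angles_deg):
            raise ValueError(
                f"{len(self.images)} images but {len(self.filter_angles_deg)} filter angles"
            )
        shape = self.images[0].shape
        for i, im in enumerate(self.images):
            if im.ndim != 2:
                raise ValueError(f"image {i} is not 2-D (shape {im.shape})")
            if im.shape != shape:
                raise ValueError(f"image {i} shape {im.shape} differs from {shape}")
            if np.any(im < 0):
                raise ValueError(f"image {i} contains negative luminance values")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if self.capture_distance_m <= 0:
            raise ValueError("capture_distance_m must be positive")

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def angles_rad(self) -> np.ndarray:
        return np.radians(np.asarray(self.filter_angles_deg))

    def index_of_angle(self, angle_deg: float) -> int:
        """Index of the first image at ``angle_deg`` (exact match)."""
        for i, a in enumerate(self.filter_angles_deg):
            if a == angle_deg:
                return i
        raise KeyError(f"no image at filter angle {angle_deg}°")

    def stack(self) -> np.ndarray:
        """Images as one (n_images, rows, cols) array."""
        return np.stack(self.images)


def rgb_to_luma(rgb_image: np.ndarray) -> np.ndarray:
    """Convert a linear RGB image to a CIE-luminance proxy.

    Weighted channel sum with Rec. 601 weights (0.2989 R, 0.5870 G,
    0.1140 B), the definition used by MATLAB's ``rgb2gray``. Linear:
    ``rgb_to_luma(α·P) == α·rgb_to_luma(P)``.
    """
    rgb = np.asarray(rgb_image, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (rows, cols, 3) RGB image, got shape {rgb.shape}")
    return rgb @ LUMA_WEIGHTS


def load_series(
    paths: Sequence[str | os.PathLike],
    angles_deg: Sequence[float],
    pixels_per_degree: float,
    capture_distance_m: float,
    exposure_locked: bool = True,
    metadata: dict[str, Any] | None = None,
) -> PolarizerSeries:
    """Read a polarizer series from per-angle TIFF files.

    Accepts 16-bit (or any integer/float) grayscale or RGB TIFFs. RGB
    is converted to luminance with :func:`rgb_to_luma`; integer counts
    are promoted to float64 *without rescaling*, since absolute scale
    is unknown and all derived quantities are ratios.
    """
    if len(paths) != len(angles_deg):
        raise ValueError(f"{len(paths)} files but {len(angles_deg)} filter angles")
    images = []
    for p in paths:
        try:
            arr = tifffile.imread(os.fspath(p))
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read TIFF {p!r}: {exc}") from exc
        if arr.ndim == 3:
            arr = rgb_to_luma(arr)
        elif arr.ndim != 2:
            raise ValueError(f"{p!r}: unsupported image dimensionality {arr.ndim}")
        images.append(np.asarray(arr, dtype=np.float64))
    return PolarizerSeries(
        images=images,
        filter_angles_deg=angles_deg,
        pixels_per_degree=pixels_per_degree,
        capture_distance_m=capture_distance_m,
        exposure_locked=exposure_locked,
        metadata=metadata or {},
    )


def save_series(series: PolarizerSeries, directory: str | os.PathLike, prefix: str = "frame") -> list[str]:
    """Write the series as per-angle 16-bit grayscale TIFFs.

    Values are rounded to uint16; raises if any value falls outside
    [0, 65535]. Returns the written paths in series order.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, (im, angle) in enumerate(zip(series.images, series.filter_angles_deg)):
        if im.min() < 0 or im.max() > 65535:
            raise ValueError(f"image {i} out of uint16 range [{im.min()}, {im.max()}]")
        path = os.path.join(directory, f"{prefix}_{i:02d}_{int(round(angle)):+04d}deg.tif")
        tifffile.imwrite(path, np.round(im).astype(np.uint16))
        paths.append(path)
    return paths


def replicate_endpoint_check(
    series: PolarizerSeries,
    roi=None,
    class_masks: dict[str, np.ndarray] | None = None,
) -> dict[str, dict[str, float]]:
    """Measurement-reliability report from the replicate ±90° endpoints.

    The −90° and +90° images are independent observations of the same
    physical condition (the polarizer has period 180°), so the mean-
    luminance difference between them within an ROI estimates repeat
    reliability. Reliability improves with ROI area as photon/sensor
    noise averages out.

    Parameters
    ----------
    series
        Must contain both a −90° and a +90° image.
    roi
        Optional :class:`~polstripe.segmentation.RegionOfInterest`
        restricting the comparison; whole frame if omitted.
    class_masks
        Optional ``{label: boolean mask}`` over the ROI window (e.g.
        black/white stripe masks) for per-class reporting.

    Returns
    -------
    dict
        Per class label (plus ``"all"``):
        ``{"abs_diff": ..., "rel_diff": ..., "mean": ...}`` where
        ``rel_diff = abs_diff / mean`` of the two endpoint means.
    """
    try:
        i_lo = series.index_of_angle(-90.0)
        i_hi = series.index_of_angle(+90.0)
    except KeyError as exc:
        raise ValueError("series lacks a replicate endpoint image (need both −90° and +90°)") from exc
    if i_lo == i_hi:
        raise ValueError("−90° and +90° endpoints must be distinct images")

    if roi is not None:
        win_lo = roi.window(series.images[i_lo], i_lo)
        win_hi = roi.window(series.images[i_hi], i_hi)
    else:
        win_lo, win_hi = series.images[i_lo], series.images[i_hi]

    def _entry(m_lo: float, m_hi: float) -> dict[str, float]:
        mean = 0.5 * (m_lo + m_hi)
        abs_diff = abs(m_hi - m_lo)
        return {
            "abs_diff": float(abs_diff),
            "rel_diff": float(abs_diff / mean) if mean > 0 else float("nan"),
            "mean": float(mean),
        }

    report = {"all": _entry(float(win_lo.mean()), float(win_hi.mean()))}
    if class_masks:
        for label, mask in class_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != win_lo.shape:
                raise ValueError(f"mask {label!r} shape {mask.shape} != window {win_lo.shape}")
            if not mask.any():
                raise ValueError(f"mask {label!r} selects no pixels")
            report[label] = _entry(float(win_lo[mask].mean()), float(win_hi[mask].mean()))
    return report
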
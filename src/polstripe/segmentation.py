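"""Stripe segmentation and ROI handling.

Each rectangular region of interest (ROI) on the animal is split into
black-stripe and white-stripe pixel sets by Otsu's criterion: the
luminance threshold that maximizes between-class variance relative to
within-class variance over a 256-bin histogram (the behaviour of
MATLAB's ``graythresh``). The threshold is recomputed independently
for every image in the series, so segmentation adapts to the large
luminance changes the rotating polarizer induces — especially in white
stripes — while the *class identity* (which pixels are "white") is
anchored to a reference image so labels cannot swap across the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import match_template

from .series_io import PolarizerSeries


@dataclass
class RegionOfInterest:
    """A tracked rectangular body-region window.

    ``rect`` is (row0, col0, height, width), 0-based, half-open.
    ``per_image_offsets`` holds one integer (drow, dcol) per image to
    follow the subject between exposures; offsets default to zero.
    """

    label: str
    rect: tuple[int, int, int, int]
    per_image_offsets: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        r0, c0, h, w = self.rect
        if h < 8 or w < 8:
            raise ValueError(f"ROI {self.label!r}: height and width must be ≥ 8 px, got {h}×{w}")
        if r0 < 0 or c0 < 0:
            raise ValueError(f"ROI {self.label!r}: rect origin must be non-negative")

    def offset_for(self, image_index: int) -> tuple[int, int]:
        if self.per_image_offsets is None:
            return (0, 0)
        return self.per_image_offsets[image_index]

    def window(self, image: np.ndarray, image_index: int = 0) -> np.ndarray:
        """The ROI pixel window in one image, offset applied."""
        r0, c0, h, w = self.rect
        dr, dc = self.offset_for(image_index)
        r0, c0 = r0 + dr, c0 + dc
        if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
            raise ValueError(
                f"ROI {self.label!r} rect+offset ({r0},{c0},{h},{w}) outside image {image.shape}"
            )
        return image[r0 : r0 + h, c0 : c0 + w]


@dataclass
class StripeSegmentation:
    """One image's black/white split of an ROI.

    ``mask`` is True for white-stripe pixels; ``threshold`` is the
    luminance cut that produced it; ``fractions`` is (white, black)
    pixel proportions.
    """

    threshold: float
    mask: np.ndarray
    fractions: tuple[float, float]

    @property
    def white_fraction(self) -> float:
        return self.fractions[0]


@dataclass
class RoiSegmentation:
    """Per-image segmentations of one ROI plus exclusion status."""

    roi: RegionOfInterest
    per_image: list[StripeSegmentation]
    excluded: bool = False
    reason: str = ""

    def masks(self) -> list[np.ndarray]:
        return [s.mask for s in self.per_image]


def otsu_from_histogram(counts: np.ndarray, bin_edges: np.ndarray) -> float:
    """Otsu threshold from a precomputed histogram.

    Evaluates every cut point between adjacent bins, maximizing the
    between-class variance w0·w1·(μ0−μ1)²; ties are broken in favour of
    the lower threshold. Returns the bin edge separating the classes,
    with the convention that values ``>= threshold`` are the upper
    (white) class.
    """
    counts = np.asarray(counts, dtype=np.float64)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if counts.ndim != 1 or len(bin_edges) != len(counts) + 1:
        raise ValueError("counts must be 1-D with len(bin_edges) == len(counts) + 1")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (counts @ centers - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    if not np.isfinite(sigma_b).any():
        raise ValueError("histogram has fewer than two occupied bins")
    # first cut within fp tolerance of the max ⇒ lowest threshold on ties
    # (cuts across runs of empty bins have mathematically equal variance)
    m = float(sigma_b.max())
    k = int(np.argmax(sigma_b >= m - 1e-9 * abs(m) - 1e-12))
    return float(bin_edges[k + 1])


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of a luminance sample over a 256-bin histogram.

    The histogram spans the sample's own range (adaptive per image, as
    ``graythresh`` applied to a normalized ROI). Raises on (near-)
    constant input, which has no bimodal structure to split.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("constant input: no threshold exists")
    counts, edges = np.histogram(v, bins=nbins, range=(vmin, vmax))
    return otsu_from_histogram(counts, edges)


def _segment_window(window: np.ndarray) -> StripeSegmentation:
    thr = otsu_threshold(window)
    mask = window >= thr
    n = mask.size
    return StripeSegmentation(
        threshold=thr,
        mask=mask,
        fractions=(float(mask.sum()) / n, float((~mask).sum()) / n),
    )


def segment_roi(
    series: PolarizerSeries,
    roi: RegionOfInterest,
    min_class_fraction: float = 0.02,
    min_class_contrast: float = 0.05,
) -> RoiSegmentation:
    """Segment an ROI into black/white stripes in every series image.

    A threshold is computed independently per image; the white label is
    anchored to the image whose filter angle is closest to 0° and
    propagated by spatial agreement, so polarization-induced luminance
    changes cannot swap the classes. The ROI is *excluded* (flagged,
    not raised) when any image fails to show two usable classes:
    a class empty or below ``min_class_fraction``, or Michelson
    contrast between class means below ``min_class_contrast`` (an ROI
    covering a single stripe splits only noise).
    """
    segs: list[StripeSegmentation] = []
    ref_idx = int(np.argmin(np.abs(np.asarray(series.filter_angles_deg))))

    for i, im in enumerate(series.images):
        window = roi.window(im, i)
        try:
            seg = _segment_window(window)
        except ValueError as exc:
            return RoiSegmentation(roi, [], excluded=True, reason=f"image {i}: {exc}")
        segs.append(seg)

    # anchor class identity to the reference (≈0°) image
    ref_mask = segs[ref_idx].mask
    for i, seg in enumerate(segs):
        agree = float((seg.mask == ref_mask).mean())
        if agree < 0.5:
            seg.mask = ~seg.mask
            seg.fractions = (seg.fractions[1], seg.fractions[0])

    for i, seg in enumerate(segs):
        window = roi.window(series.images[i], i)
        wf, bf = seg.fractions
        if min(wf, bf) < min_class_fraction:
            return RoiSegmentation(
                roi, segs, excluded=True,
                reason=f"image {i}: class fraction {min(wf, bf):.3f} below {min_class_fraction}",
            )
        lw = float(window[seg.mask].mean())
        lb = float(window[~seg.mask].mean())
        contrast = abs(lw - lb) / (lw + lb) if lw + lb > 0 else 0.0
        if contrast < min_class_contrast:
            return RoiSegmentation(
                roi, segs, excluded=True,
                reason=f"image {i}: class contrast {contrast:.3f} below {min_class_contrast} "
                "(single stripe or luminance artifact)",
            )
    return RoiSegmentation(roi, segs)


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a boolean stripe mask as an 8-bit PNG (white stripe = 255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def track_roi(
    series: PolarizerSeries, roi: RegionOfInterest, search_radius: int = 5
) -> list[tuple[int, int]]:
    """Recover per-image ROI offsets by normalized cross-correlation.

    The ROI patch from the first image is matched against a search
    window of ±``search_radius`` px in every other image; the
    correlation peak gives the (drow, dcol) offset. A peak on the
    search boundary triggers a warning (the true displacement may
    exceed the radius). Config-specified offsets should take precedence
    over tracking; this is an automated stand-in for manual matching
    on fiduciary marks.
    """
    if search_radius < 0:
        raise ValueError("search_radius must be ≥ 0")
    r0, c0, h, w = roi.rect
    offsets: list[tuple[int, int]] = [(0, 0)]
    if search_radius == 0:
        return [(0, 0)] * series.n_images
    template = series.images[0][r0 : r0 + h, c0 : c0 + w]
    H, W = series.shape
    rs, cs = max(r0 - search_radius, 0), max(c0 - search_radius, 0)
    re, ce = min(r0 + h + search_radius, H), min(c0 + w + search_radius, W)
    for i in range(1, series.n_images):
        window = series.images[i][rs:re, cs:ce]
        corr = match_template(window, template)
        peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
        dr = int(peak[0]) + rs - r0
        dc = int(peak[1]) + cs - c0
        if peak[0] in (0, corr.shape[0] - 1) or peak[1] in (0, corr.shape[1] - 1):
            warnings.warn(
                f"ROI {roi.label!r}, image {i}: correlation peak on search boundary "
                f"(offset ({dr}, {dc}) may exceed search_radius={search_radius})",
                stacklevel=2,
            )
        offsets.append((dr, dc))
    return offsets
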
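"""Ex vivo organ, IHC and histology quantification.

Covers the arithmetic behind the imaging readouts: mean fluorescence
intensity (MFI) over regions of interest with cohort-wide min-max
normalisation, distal/proximal segmentation of a resected-colon mask along
its long axis, percent-positive-pixel IHC area fractions (Iba-1, NE), and
histology interval arithmetic (total erosion length; inflammation extent
measured proximally from the rectal squamous junction).

Pixel classification itself (which pixels are marker-positive, where the
organ is) is upstream; this module consumes masks, areas and intensity
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ErosionProfile",
    "roi_mfi",
    "min_max_normalize",
    "segment_rois",
    "positive_fraction",
    "total_erosion_length",
    "inflammation_extent",
]


class QuantError(ValueError):
    """Invalid mask, interval or area input."""


def roi_mfi(intensities: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean fluorescence intensity of a region of interest.

    ``intensities`` is any-dimensional; ``mask`` (boolean, same shape)
    restricts to the ROI. Empty ROIs are an error, not NaN.
    """
    img = np.asarray(intensities, float)
    if mask is not None:
        m = np.asarray(mask, bool)
        if m.shape != img.shape:
            raise QuantError("mask shape must match intensity shape")
        img = img[m]
    if img.size == 0:
        raise QuantError("empty ROI")
    return float(img.sum() / img.size)


def min_max_normalize(values: np.ndarray) -> np.ndarray:
    """Cohort-wide min-max transform: (x - min) / (max - min), into [0, 1]."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise QuantError("min-max normalization needs >= 2 values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise QuantError("all values equal: min-max scale undefined")
    return (x - lo) / (hi - lo)


def segment_rois(
    mask: np.ndarray, split_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Split an organ mask into distal and proximal halves along its long axis.

    The long axis is the larger bounding-box extent; pixels whose axis
    coordinate lies below ``min + split_fraction * extent`` form the distal
    submask (the rectal end at the lower coordinate), the rest the proximal
    one.  The two submasks partition the input exactly.
    """
    m = np.asarray(mask, bool)
    if m.ndim != 2:
        raise QuantError("mask must be 2-D")
    if not 0.0 < split_fraction < 1.0:
        raise QuantError("split fraction must be strictly between 0 and 1")
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise QuantError("empty organ mask")
    extents = (rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
    axis_coord = rows if extents[0] >= extents[1] else cols
    lo = axis_coord.min()
    extent = axis_coord.max() - lo + 1
    if extent < 2:
        raise QuantError("degenerate mask: long axis shorter than 2 pixels")
    cutoff = lo + split_fraction * extent

    distal = np.zeros_like(m)
    proximal = np.zeros_like(m)
    below = axis_coord < cutoff
    distal[rows[below], cols[below]] = True
    proximal[rows[~below], cols[~below]] = True
    return distal, proximal


def positive_fraction(marker_area: float, mucosal_area: float) -> float:
    """IHC percent-positive pixels: 100 * marker area / total mucosal area."""
    if mucosal_area <= 0:
        raise QuantError("mucosal area must be > 0")
    if not 0 <= marker_area <= mucosal_area:
        raise QuantError("marker area must be within [0, mucosal area]")
    return min(100.0 * marker_area / mucosal_area, 100.0)


@dataclass
class ErosionProfile:
    """Histology profile of one colon, measured from the rectal junction.

    ``erosions`` are half-open (start, end) intervals in mm along the colon;
    ``positions``/``loss_fraction`` give a piecewise-constant crypt-loss
    profile (value holds from each position to the next, the last to
    ``length_mm``).
    """

    length_mm: float
    erosions: list[tuple[float, float]] = field(default_factory=list)
    positions: np.ndarray | None = None
    loss_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise QuantError("colon length must be > 0")
        for s, e in self.erosions:
            if not (0 <= s < e <= self.length_mm):
                raise QuantError(f"erosion interval ({s}, {e}) outside [0, {self.length_mm}]")
        if (self.positions is None) != (self.loss_fraction is None):
            raise QuantError("positions and loss_fraction must be given together")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, float)
            self.loss_fraction = np.asarray(self.loss_fraction, float)
            if self.positions.size != self.loss_fraction.size:
                raise QuantError("positions and loss_fraction lengths differ")
            if np.any(np.diff(self.positions) <= 0):
                raise QuantError("positions must be strictly increasing")
            if np.any((self.loss_fraction < 0) | (self.loss_fraction > 1)):
                raise QuantError("loss fractions must be in [0, 1]")


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    srt = sorted(intervals)
    merged = [list(srt[0])]
    for s, e in srt[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def total_erosion_length(profile: ErosionProfile) -> float:
    """Summed length (mm) of all erosions, overlaps merged first."""
    return float(sum(e - s for s, e in _merge_intervals(profile.erosions)))


def inflammation_extent(profile: ErosionProfile, threshold: float = 0.5) -> float:
    """Length of colon, contiguous from the rectal junction, with crypt loss
    above threshold.

    The rule walks proximally from position 0 and stops at the first segment
    whose loss fraction is <= threshold; disease further up the colon that is
    not contiguous with the junction does not count.
    """
    if profile.positions is None:
        raise QuantError("profile lacks a crypt-loss profile")
    pos = profile.positions
    loss = profile.loss_fraction
    if pos[0] > 0:
        return 0.0  # profile does not start at the junction
    extent = 0.0
    for i, value in enumerate(loss):
        seg_end = pos[i + 1] if i + 1 < pos.size else profile.length_mm
        if value > threshold:
            extent = seg_end
        else:
            break
    return float(min(extent, profile.length_mm))
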
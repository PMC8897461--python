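"""Microglia morphometry and dendrite-microglia colocalization on 2-D images.

Segmentation follows the triangle algorithm: the threshold is the histogram
bin with maximal perpendicular distance to the chord drawn from the histogram
peak to the far end of its longer tail.  Per-cell shape metrics are the
ramification index (perimeter over the perimeter of the equal-area circle;
1 for a disc), total tree length (skeleton path length), spanned area (convex
hull) and total area.  Colocalization of dendrite (green) and microglia
(red) channels is the yellow / (yellow + green) pixel ratio inside dendrite
segments of at least 30 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.morphology import skeletonize

__all__ = [
    "DegenerateHistogramError",
    "MicrogliaMetrics",
    "ColocResult",
    "triangle_threshold",
    "threshold_image",
    "colocalization_fraction",
    "microglia_cell_metrics",
    "skeleton_length_px",
    "coverage_fraction",
]

MIN_SEGMENT_LENGTH_UM = 30.0

_SQRT2 = float(np.sqrt(2.0))


class DegenerateHistogramError(ValueError):
    """Histogram has no triangle geometry (flat or fewer than two bins)."""


def triangle_threshold(histogram) -> int:
    """Triangle-algorithm threshold of an intensity histogram.

    The chord runs from the peak bin to the farthest nonzero bin on the
    longer-tail side; the threshold is the bin between them whose count lies
    farthest below the chord (perpendicular distance).  Ties are broken
    toward the tail.  Returns the bin index.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if (h < 0).any():
        raise ValueError("histogram counts must be >= 0")
    nz = np.flatnonzero(h)
    if nz.size < 2:
        raise DegenerateHistogramError("need at least two nonzero bins")
    peak = int(np.argmax(h))
    left, right = peak - nz[0], nz[-1] - peak
    # longer tail wins; on a tie the high-intensity side is used
    if right >= left:
        lo, hi, tail_sign = peak, int(nz[-1]), +1
    else:
        lo, hi, tail_sign = int(nz[0]), peak, -1
    if hi == lo:
        raise DegenerateHistogramError("peak coincides with the tail end")
    # distance from (x, h[x]) to the chord (lo,h[lo])-(hi,h[hi]), up to a
    # positive factor: |cross product| of chord with point offset
    x = np.arange(lo, hi + 1)
    dx, dy = hi - lo, h[hi] - h[lo]
    d = np.abs(dy * (x - lo) - dx * (h[lo:hi + 1] - h[lo]))
    if np.max(d) <= 0:
        raise DegenerateHistogramError("flat histogram segment; no triangle geometry")
    if tail_sign > 0:
        best = int(x[len(d) - 1 - int(np.argmax(d[::-1]))])  # last argmax -> toward tail
    else:
        best = int(x[int(np.argmax(d))])  # first argmax -> toward (left) tail
    return best


def threshold_image(image, n_bins: int | None = None) -> tuple[np.ndarray, int]:
    """Binarize an intensity image with the triangle threshold.

    The histogram is built over integer intensities (or ``n_bins`` equal
    bins); pixels strictly above the threshold are foreground.  Returns
    (mask, threshold).
    """
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer) and n_bins is None:
        hist = np.bincount(img.ravel())
        thr = triangle_threshold(hist)
        return img > thr, int(thr)
    n_bins = n_bins or 256
    hist, edges = np.histogram(img.ravel(), bins=n_bins)
    idx = triangle_threshold(hist)
    thr_value = edges[idx + 1]
    return img > thr_value, idx


@dataclass(frozen=True)
class ColocResult:
    fraction: float
    n_yellow: int
    n_green_only: int
    undefined: bool


def colocalization_fraction(
    mask_red: np.ndarray,
    mask_green: np.ndarray,
    roi: np.ndarray,
    roi_length_um: float | None = None,
    min_length_um: float = MIN_SEGMENT_LENGTH_UM,
) -> ColocResult:
    """Yellow / (yellow + green) pixel ratio within a dendrite segment ROI.

    Yellow pixels are above threshold in both channels; green-only pixels are
    green but not red.  A segment shorter than 30 um is rejected; an ROI
    without green pixels yields an undefined (NaN) fraction.
    """
    if mask_red.shape != mask_green.shape or mask_red.shape != roi.shape:
        raise ValueError("channel masks and ROI must share one shape")
    if roi_length_um is not None and roi_length_um < min_length_um:
        raise ValueError(
            f"segment length {roi_length_um:.1f} um below the {min_length_um} um minimum"
        )
    red = np.asarray(mask_red, bool)
    green = np.asarray(mask_green, bool)
    roi = np.asarray(roi, bool)
    yellow = int(np.count_nonzero(red & green & roi))
    green_only = int(np.count_nonzero(green & ~red & roi))
    total = yellow + green_only
    if total == 0:
        return ColocResult(float("nan"), 0, 0, True)
    return ColocResult(yellow / total, yellow, green_only, False)


@dataclass(frozen=True)
class MicrogliaMetrics:
    ramification_index: float
    tree_length_um: float
    spanned_area_um2: float
    total_area_um2: float


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Path length of a thin 8-connected skeleton, in pixels.

    Orthogonal neighbor steps count 1, diagonal steps sqrt(2); a diagonal is
    skipped when both flanking orthogonal links exist (avoids double counting
    around corners).
    """
    sk = np.asarray(skeleton, bool)
    p = np.pad(sk, 1)
    e = p[1:-1, 2:]    # east neighbor
    s = p[2:, 1:-1]    # south
    w = p[1:-1, :-2]   # west
    se = p[2:, 2:]
    sw = p[2:, :-2]
    core = p[1:-1, 1:-1]
    n_orth = np.count_nonzero(core & e) + np.count_nonzero(core & s)
    diag_se = core & se & ~(e & s)
    diag_sw = core & sw & ~(w & s)
    n_diag = np.count_nonzero(diag_se) + np.count_nonzero(diag_sw)
    return n_orth + _SQRT2 * n_diag


def _hull_area_px2(mask: np.ndarray) -> float:
    """Convex-hull area of the mask's pixel squares (centers +/- 0.5)."""
    pts = np.argwhere(mask).astype(float)
    corners = np.concatenate([pts + off for off in
                              ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])])
    try:
        return float(ConvexHull(corners).volume)
    except QhullError:  # pragma: no cover - degenerate single-pixel input
        return float(np.count_nonzero(mask))


def microglia_cell_metrics(
    cell_mask: np.ndarray,
    pixel_size_um: float,
    perimeter_method: str = "crofton",
) -> MicrogliaMetrics:
    """Shape metrics of one pre-separated microglial cell mask.

    total area: pixel count x pixel area; spanned area: convex hull of the
    pixel squares (so total <= spanned always); tree length: skeleton path
    length; ramification index: perimeter / (2 * sqrt(pi * area_px)), i.e.
    the cell's perimeter relative to that of an equal-area circle.  The
    perimeter uses the Crofton 4-direction estimator by default
    (``perimeter_method='crack'`` selects weighted boundary-crack counting).
    """
    mask = np.asarray(cell_mask, bool)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n_px = int(np.count_nonzero(mask))
    if n_px == 0:
        raise ValueError("empty cell mask")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"cell mask must be a single connected component, got {n_comp}")
    if perimeter_method == "crofton":
        perim = float(measure.perimeter_crofton(mask, directions=4))
    elif perimeter_method == "crack":
        perim = float(measure.perimeter(mask))
    else:
        raise ValueError("perimeter_method must be 'crofton' or 'crack'")
    ri = perim / (2.0 * np.sqrt(np.pi * n_px))
    tree_px = skeleton_length_px(skeletonize(mask))
    px2 = pixel_size_um**2
    return MicrogliaMetrics(
        ramification_index=float(ri),
        tree_length_um=float(tree_px * pixel_size_um),
        spanned_area_um2=float(_hull_area_px2(mask) * px2),
        total_area_um2=float(n_px * px2),
    )


def coverage_fraction(mask: np.ndarray, region: np.ndarray) -> float:
    """Fraction of region pixels that are above threshold in ``mask``."""
    mask = np.asarray(mask, bool)
    region = np.asarray(region, bool)
    if mask.shape != region.shape:
        raise ValueError("mask and region must share one shape")
    n_region = int(np.count_nonzero(region))
    if n_region == 0:
        raise ValueError("empty region")
    return float(np.count_nonzero(mask & region) / n_region)
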
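"""Histogram auto-thresholding and mask utilities.

The two threshold operators reproduce the histogram-based auto-threshold
functions of the Fiji/ImageJ toolchain as used in the quantification
workflows: Otsu's between-class-variance criterion and the
Kapur–Sahoo–Wong maximum-entropy criterion. Both operate on a 256-bin
histogram spanning the data's min–max range (the 8-bit convention of
that toolchain) and search every candidate split exhaustively, so they
are exactly the argmax of their criterion; ties are broken toward the
smallest level, and foreground is "strictly greater than threshold".

Also here: the 2-px-radius circular mean filter and min–max contrast
stretch used to prepare segmentation copies of frames, connected-
component selection (8-connectivity, matching ImageJ particle
analysis), and Chebyshev ("expand by k pixels in each direction")
ROI dilation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Roi

__all__ = [
    "Histogram",
    "build_histogram",
    "otsu_threshold",
    "max_entropy_threshold",
    "threshold_mask",
    "mean_filter",
    "contrast_stretch",
    "mask_to_roi",
    "expand_roi",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class Histogram:
    """Intensity histogram with explicit bin edges.

    ``integer_levels`` is True when the bins are unit-width integer
    levels (bin ``i`` collects exactly the value ``bin_edges[i]``), the
    case for 8-bit-like data; otherwise bins partition [min, max] into
    ``n_bins`` equal-width intervals, last bin closed.
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    integer_levels: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram count")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def level_value(self, t: int) -> float:
        """Raw-intensity threshold for the split "background = bins <= t".

        Foreground is defined as pixel value strictly greater than the
        returned value.
        """
        if self.integer_levels:
            return float(self.bin_edges[t])
        return float(self.bin_edges[t + 1])


def build_histogram(pixels: np.ndarray, n_bins: int = 256) -> Histogram:
    """Histogram the given pixels into ``n_bins`` bins over their min–max range.

    Integer data whose value range fits within ``n_bins`` gets unit-width
    integer-level bins starting at the data minimum (so for 8-bit data on
    256 bins the bins are the integer levels); other data gets equal-width
    bins spanning [min, max].
    """
    pixels = np.asarray(pixels).ravel()
    if pixels.size == 0:
        raise ValueError("cannot histogram zero pixels")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vmin, vmax = pixels.min(), pixels.max()

    integer_data = np.issubdtype(pixels.dtype, np.integer)
    if integer_data and (int(vmax) - int(vmin)) < n_bins:
        counts = np.bincount((pixels - vmin).astype(np.int64), minlength=n_bins)
        edges = np.arange(int(vmin), int(vmin) + n_bins + 1, dtype=np.float64)
        return Histogram(counts=counts, bin_edges=edges, integer_levels=True)

    if vmin == vmax:
        # constant non-integer data: all mass in the first bin
        edges = np.linspace(float(vmin), float(vmin) + 1.0, n_bins + 1)
        counts = np.zeros(n_bins, dtype=np.int64)
        counts[0] = pixels.size
        return Histogram(counts=counts, bin_edges=edges)

    counts, edges = np.histogram(pixels, bins=n_bins, range=(float(vmin), float(vmax)))
    return Histogram(counts=counts, bin_edges=edges)


def _smallest_argmax(crit: np.ndarray, rel_tol: float = 1e-10) -> int:
    """Smallest index whose criterion is within rounding error of the maximum.

    Symmetric histograms can tie two distinct splits exactly in real
    arithmetic; float evaluation breaks such ties arbitrarily, so the
    tie-break ("smallest maximizing level") is applied within a relative
    tolerance of the maximum.
    """
    m = crit.max()
    return int(np.argmax(crit >= m - rel_tol * max(1.0, abs(m))))


def _check_thresholdable(hist: Histogram) -> None:
    if int(np.count_nonzero(hist.counts)) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")


def otsu_threshold(hist: Histogram) -> int:
    """Otsu's threshold: the split index t maximizing between-class variance.

    Background is bins <= t; the criterion is
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` over bin indices. Every
    candidate split is evaluated; ties go to the smallest t. Use
    :meth:`Histogram.level_value` to map t back to a raw intensity.
    """
    _check_thresholdable(hist)
    p = hist.counts.astype(np.float64) / hist.total
    levels = np.arange(hist.n_bins, dtype=np.float64)
    cum_w = np.cumsum(p)
    cum_m = np.cumsum(p * levels)
    w0 = cum_w[:-1]                 # background weight for t = 0..n-2
    m0 = cum_m[:-1]                 # background first moment
    mu_total = cum_m[-1]            # same accumulation as m0, so plateau ties are exact
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    crit = np.zeros(hist.n_bins - 1)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=valid)
    mu1 = np.divide(mu_total - m0, w1, out=np.zeros_like(m0), where=valid)
    crit[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    return _smallest_argmax(crit)


def max_entropy_threshold(hist: Histogram) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold.

    Returns the split index t maximizing the sum of the Shannon
    entropies of the renormalized background (bins <= t) and foreground
    (bins > t) distributions, searched over every split that leaves both
    classes non-empty. Ties go to the smallest t.
    """
    _check_thresholdable(hist)
    p = hist.counts.astype(np.float64) / hist.total
    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    cum_full_p = np.cumsum(p)
    cum_full_plogp = np.cumsum(plogp)
    cum_p = cum_full_p[:-1]
    cum_plogp = cum_full_plogp[:-1]
    tot_plogp = cum_full_plogp[-1]  # same accumulation as cum_plogp

    # integer cumulative counts decide side emptiness exactly; only splits
    # with both classes non-empty are candidates (the degenerate splits
    # would trivially score the total entropy), matching the named tool
    n0 = np.cumsum(hist.counts)[:-1]
    proper = (n0 > 0) & (n0 < hist.total)

    w0, w1 = cum_p, 1.0 - cum_p
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = -cum_plogp / w0 + np.log(w0)
        h1 = -(tot_plogp - cum_plogp) / w1 + np.log(w1)
    crit = np.where(proper, h0 + h1, -np.inf)
    return _smallest_argmax(crit)


def threshold_mask(frame: np.ndarray, hist: Histogram, t: int) -> np.ndarray:
    """Foreground mask: pixels strictly greater than the threshold level t."""
    return np.asarray(frame) > hist.level_value(t)


def mean_filter(frame: np.ndarray, radius_px: int = 2) -> np.ndarray:
    """Circular mean filter (ImageJ "Mean" semantics).

    Each pixel is replaced by the mean over the disk neighbourhood
    ``{(dx, dy): dx**2 + dy**2 <= r**2}``; at the image edge the mean is
    taken over the in-bounds members only, so constant frames are fixed
    points and output values never leave the input's [min, max] range.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = (xx**2 + yy**2 <= r**2).astype(np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    num = ndimage.correlate(frame, footprint, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(frame), footprint, mode="constant", cval=0.0)
    return num / den


def contrast_stretch(frame: np.ndarray, out_max: float = 255.0) -> np.ndarray:
    """Linear min–max stretch to [0, out_max]; monotone and rank-preserving.

    A constant frame cannot be stretched and is returned unchanged with
    a warning. Used only on segmentation copies of frames, never on
    pixels being quantified.
    """
    frame = np.asarray(frame, dtype=np.float64)
    vmin, vmax = frame.min(), frame.max()
    if vmin == vmax:
        warnings.warn("contrast_stretch: constant frame returned unchanged")
        return frame.copy()
    return (frame - vmin) / (vmax - vmin) * out_max


def _component_masks(mask: np.ndarray) -> list[np.ndarray]:
    labels, n = ndimage.label(np.asarray(mask).astype(bool), structure=EIGHT_CONNECTED)
    return [labels == i for i in range(1, n + 1)]


def mask_to_roi(
    mask: np.ndarray,
    mode: str = "largest_component",
    seed_point: tuple[float, float] | None = None,
) -> Roi:
    """Select one 8-connected component of a binary mask as a mask ROI.

    ``mode="largest_component"`` takes the component with the most
    pixels; ``mode="nearest_to_seed"`` takes the component whose
    centroid is nearest ``seed_point`` (an (x, y) pair).
    """
    comps = _component_masks(mask)
    if not comps:
        raise ValueError("no foreground in mask")
    if mode == "largest_component":
        best = max(comps, key=lambda c: int(c.sum()))
    elif mode == "nearest_to_seed":
        if seed_point is None:
            raise ValueError("nearest_to_seed mode requires a seed_point")
        sx, sy = seed_point

        def dist(c: np.ndarray) -> float:
            cy, cx = ndimage.center_of_mass(c)
            return float((cx - sx) ** 2 + (cy - sy) ** 2)

        best = min(comps, key=dist)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Roi.from_mask(best)


def expand_roi(roi: Roi, k_px: int, image_shape: tuple[int, int]) -> Roi:
    """Dilate a ROI by ``k_px`` pixels in each direction (Chebyshev distance).

    Equivalent to dilation with a (2k+1)x(2k+1) square structuring
    element, clipped to the image bounds; the result always contains the
    input. Rectangles stay rectangles; mask ROIs stay masks.
    """
    if k_px < 1:
        raise ValueError("k_px must be >= 1")
    h, w = image_shape
    if roi.kind == "rect":
        x0 = max(0, roi.x0 - k_px)
        y0 = max(0, roi.y0 - k_px)
        x1 = min(w, roi.x0 + roi.width + k_px)
        y1 = min(h, roi.y0 + roi.height + k_px)
        return Roi.rectangle(x0, y0, x1 - x0, y1 - y0)
    footprint = np.ones((2 * k_px + 1, 2 * k_px + 1), dtype=bool)
    dilated = ndimage.binary_dilation(roi.to_mask(image_shape), structure=footprint)
    return Roi.from_mask(dilated)
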
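"""Chromosome condensation parameter time courses.

The condensation parameter summarizes the pixel-value distribution in a
fixed square ROI (21x21 px) centred on the paternal pronucleus. Per
timepoint the ROI's values are min-max rescaled to [0, 255] and the
parameter is the fraction of rescaled values strictly below a fixed
threshold (0.4 x 255 = 102). Diffuse chromatin gives a mid-heavy
distribution and a low parameter; as chromosomes condense into a few
bright foci over dark nucleoplasm the mass shifts below the threshold
and the parameter rises toward 1. The rescaling makes the statistic
invariant to photobleaching and any positive affine change of gain or
offset.

Curves are aligned in time to nuclear envelope breakdown (NEB = t 0),
averaged across embryos per timepoint, and smoothed for display with
tricube-weighted local linear regression (loess, span 0.4).

ROI centring: each frame's max projection is contrast-stretched, mean
filtered (radius 2) and Otsu-thresholded; the centre is the centroid of
the component nearest the tracking seed. The parameter itself is always
computed on the raw, unfiltered projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .image import ImageSeries, max_project
from .segmentation import (
    build_histogram,
    contrast_stretch,
    mask_to_roi,
    mean_filter,
    otsu_threshold,
    threshold_mask,
)
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "CondensationConfig",
    "CondensationCurve",
    "AggregateCurve",
    "locate_pronucleus",
    "condensation_parameter",
    "condensation_timecourse",
    "aggregate_curves",
    "loess_smooth",
]


@dataclass(frozen=True)
class CondensationConfig:
    """Parameters of the condensation statistic.

    roi_size_px : side of the square ROI (odd so it can be centred).
    threshold_fraction : fraction of the rescaled maximum below which
        pixels count as "condensed-dark"; with rescale_max 255 the
        default 0.4 gives the cut-off value 102.
    rescale_max : upper end of the per-ROI min-max rescale.
    smoothing_span : loess span for display smoothing of aggregates.
    """

    roi_size_px: int = 21
    threshold_fraction: float = 0.4
    rescale_max: float = 255.0
    smoothing_span: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.roi_size_px < 1 or self.roi_size_px % 2 == 0:
            raise ValueError("roi_size_px must be odd and positive")
        if self.rescale_max <= 0:
            raise ValueError("rescale_max must be positive")

    @property
    def threshold(self) -> float:
        """The cut-off on the rescaled [0, rescale_max] scale (default 102)."""
        return self.threshold_fraction * self.rescale_max


@dataclass
class CondensationCurve:
    """Per-embryo, NEB-aligned condensation parameter time course."""

    embryo_id: str
    times_s: np.ndarray
    values: np.ndarray
    neb_frame: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("condensation parameter must lie in [0, 1]")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class AggregateCurve:
    """Cross-embryo mean +- sd per aligned timepoint, with loess smoothing."""

    times_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    smoothed: np.ndarray
    single_embryo_flag: bool = field(default=False)


def locate_pronucleus(
    frame: np.ndarray,
    seed_point: tuple[float, float] | None = None,
    n_bins: int = 256,
) -> tuple[int, int]:
    """Centre of the pronucleus on one (projected) frame, as integer (x, y).

    Segmentation copy: contrast stretch, circular mean filter (radius
    2), Otsu threshold. The returned centre is the centroid of the
    component nearest ``seed_point`` (largest component if no seed),
    rounded to the nearest pixel.
    """
    filtered = mean_filter(contrast_stretch(frame), radius_px=2)
    hist = build_histogram(filtered, n_bins=n_bins)
    t = otsu_threshold(hist)
    mask = threshold_mask(filtered, hist, t)
    if not mask.any():
        raise ValueError("empty segmentation mask; cannot locate pronucleus")
    mode = "nearest_to_seed" if seed_point is not None else "largest_component"
    roi = mask_to_roi(mask, mode=mode, seed_point=seed_point)
    cy, cx = ndimage.center_of_mass(roi.mask)
    return int(round(cx)), int(round(cy))


def condensation_parameter(
    roi_pixels: np.ndarray, config: CondensationConfig = CondensationConfig()
) -> float:
    """Fraction of min-max rescaled ROI pixels strictly below the cut-off.

    Values are rescaled so min -> 0 and max -> rescale_max (kept as real
    numbers, no re-binning), then the fraction with rescaled value <
    threshold (102 at defaults) is returned. A constant ROI has no
    visible condensation and returns 0.0 by convention.
    """
    v = np.asarray(roi_pixels, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    if v.size < 2:
        raise ValueError("condensation parameter needs at least 2 pixels")
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        return 0.0
    rescaled = (v - vmin) / (vmax - vmin) * config.rescale_max
    return float(np.mean(rescaled < config.threshold))


def _centered_window(frame: np.ndarray, cx: int, cy: int, size: int) -> np.ndarray:
    half = size // 2
    h, w = frame.shape
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    x0, x1 = max(0, cx - half), min(w, cx + half + 1)
    return frame[y0:y1, x0:x1]


def condensation_timecourse(
    series: ImageSeries,
    neb_frame: int,
    seed_point: tuple[float, float] | None = None,
    config: CondensationConfig = CondensationConfig(),
    embryo_id: str = "",
    max_lost_frames: int = 2,
) -> CondensationCurve:
    """Condensation parameter per timepoint, aligned to NEB.

    Per frame: max projection; the pronucleus is located on a filtered
    segmentation copy (the previous centre seeds the search, so the ROI
    tracks the nucleus); the square ROI is cut from the raw projection
    and the parameter computed. If centring fails on a frame, the
    previous centre is carried forward for at most ``max_lost_frames``
    consecutive frames (logged); longer losses raise.
    """
    if not 0 <= neb_frame < len(series):
        raise ValueError(f"neb_frame {neb_frame} outside series of length {len(series)}")

    values = []
    centre = None
    seed = seed_point
    lost = 0
    for t in range(len(series)):
        proj = max_project(series.stacks[t])
        try:
            centre = locate_pronucleus(proj, seed_point=seed)
            lost = 0
        except ValueError:
            if centre is None or lost >= max_lost_frames:
                raise ValueError(
                    f"pronucleus lost at frame {t} for more than {max_lost_frames} frames"
                )
            lost += 1
            logger.warning(
                "frame %d: pronucleus not found, carrying forward centre %s", t, centre
            )
        seed = centre
        roi_pixels = _centered_window(proj, centre[0], centre[1], config.roi_size_px)
        values.append(condensation_parameter(roi_pixels, config))

    times = (np.arange(len(series)) - neb_frame) * series.dt_s
    return CondensationCurve(
        embryo_id=embryo_id, times_s=times, values=np.array(values), neb_frame=neb_frame
    )


def aggregate_curves(
    curves: list[CondensationCurve],
    dt_s: float | None = None,
    span: float = 0.4,
) -> AggregateCurve:
    """Per-timepoint mean and sample sd over embryos, plus loess smoothing.

    Curves must share the NEB-aligned time grid (equal dt, integer frame
    offsets). Timepoints covered by a single embryo report sd 0; a
    single input curve sets ``single_embryo_flag``.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    steps = [float(np.diff(c.times_s)[0]) for c in curves if len(c.times_s) > 1]
    if steps and (max(steps) - min(steps)) > 1e-9:
        raise ValueError("curves have differing frame intervals")
    dt = dt_s if dt_s is not None else (steps[0] if steps else 1.0)

    by_index: dict[int, list[float]] = {}
    for c in curves:
        for t, v in zip(c.times_s, c.values):
            k = int(round(t / dt))
            if abs(k * dt - t) > 1e-6 * max(dt, 1.0):
                raise ValueError("curve timepoints do not align to a common grid")
            by_index.setdefault(k, []).append(float(v))

    if len(curves) > 1 and all(len(vs) < 2 for vs in by_index.values()):
        raise ValueError("curves share no overlapping timepoints")

    keys = sorted(by_index)
    times = np.array([k * dt for k in keys])
    mean = np.array([np.mean(by_index[k]) for k in keys])
    sd = np.array(
        [np.std(by_index[k], ddof=1) if len(by_index[k]) > 1 else 0.0 for k in keys]
    )
    n = np.array([len(by_index[k]) for k in keys])
    smoothable = len(keys) >= 3 and math.ceil(span * len(keys)) >= 3
    smoothed = loess_smooth(times, mean, span=span) if smoothable else mean.copy()
    return AggregateCurve(
        times_s=times,
        mean=mean,
        sd=sd,
        n=n,
        smoothed=smoothed,
        single_embryo_flag=len(curves) == 1,
    )


def loess_smooth(x, y, span: float = 0.4) -> np.ndarray:
    """Locally weighted linear regression (loess, degree 1, tricube weights).

    For each point x0 the fit uses the ``ceil(span * n)`` nearest
    points, weighted by ``w = (1 - (d/d_max)**3)**3`` on their distances
    d to x0, and evaluates the weighted least-squares line at x0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have the same length")
    if n < 3:
        raise ValueError("loess needs at least 3 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = math.ceil(span * n)
    if k < 3:
        raise ValueError(f"span {span} gives a window of {k} < 3 points")

    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        if w.sum() == 0:  # degenerate window, fall back to unweighted mean
            fitted[i] = y[idx].mean()
            continue
        # weighted least squares for y = b0 + b1 * (x - x0)
        xs = x[idx] - x[i]
        sw, swx, swxx = w.sum(), (w * xs).sum(), (w * xs * xs).sum()
        swy, swxy = (w * y[idx]).sum(), (w * xs * y[idx]).sum()
        det = sw * swxx - swx * swx
        if det <= 1e-12 * max(sw * swxx, 1e-300):
            fitted[i] = swy / sw
        else:
            fitted[i] = (swxx * swy - swx * swxy) / det
    return fitted
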
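"""Per-embryo time-course metrics beyond the metaphase and condensation stages.

Covers total nuclear intensity time courses (cytoplasm-background
corrected mean pixel values over both pronuclei), spindle pole-to-pole
distances, the NEB-to-anaphase interval, FRAP average line profiles
across a half-bleached metaphase plate, and embryonic lethality from
egg/hatchling counts. Manual measurements (pole positions, event
frames, the cytoplasm region, the FRAP ROI placement) are consumed as
annotations, matching how they were produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import ImageSeries, Roi, max_project, total_intensity

__all__ = [
    "NuclearTimecourse",
    "FrapProfile",
    "LethalityRecord",
    "nuclear_timecourse",
    "pole_distance",
    "pole_distance_timecourse",
    "neb_to_anaphase_interval",
    "frap_profiles",
    "average_profiles",
    "embryonic_lethality",
]


@dataclass
class NuclearTimecourse:
    """Background-corrected mean nuclear pixel value per timepoint."""

    embryo_id: str
    times_s: np.ndarray
    mean_nuclear_value: np.ndarray
    roi_areas: np.ndarray


@dataclass
class FrapProfile:
    """Average line profile along a FRAP ROI's long axis at one timepoint."""

    label: str
    positions: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None


@dataclass
class LethalityRecord:
    replicate_id: str
    eggs_laid: int
    hatchlings: int

    def __post_init__(self) -> None:
        if self.eggs_laid <= 0:
            raise ValueError("eggs_laid must be positive")
        if self.hatchlings < 0 or self.hatchlings > self.eggs_laid:
            raise ValueError("hatchlings must satisfy 0 <= hatchlings <= eggs_laid")

    @property
    def lethality_fraction(self) -> float:
        """(laid - hatched) / laid, in [0, 1]."""
        return (self.eggs_laid - self.hatchlings) / self.eggs_laid


def nuclear_timecourse(
    gfp_series: ImageSeries,
    nuclear_rois_per_frame: list[tuple[Roi, Roi]],
    cytoplasm_roi: Roi,
    embryo_id: str = "",
) -> NuclearTimecourse:
    """Cytoplasm-corrected mean nuclear intensity over time.

    Per frame (max projection): total intensity of the maternal and
    paternal pronucleus ROIs, minus (combined nuclear area x mean pixel
    value of a 25x25 cytoplasm region), divided by the combined area to
    yield a mean pixel value. The two nuclear ROIs must not overlap.
    """
    if len(nuclear_rois_per_frame) != len(gfp_series):
        raise ValueError("need one (maternal, paternal) ROI pair per frame")
    shape = gfp_series.frame_shape
    means = np.empty(len(gfp_series))
    areas = np.empty(len(gfp_series))
    for t, (roi_m, roi_p) in enumerate(nuclear_rois_per_frame):
        if np.any(roi_m.to_mask(shape) & roi_p.to_mask(shape)):
            raise ValueError(f"maternal and paternal ROIs overlap at frame {t}")
        proj = max_project(gfp_series.stacks[t])
        area = roi_m.area_px + roi_p.area_px
        total = total_intensity(proj, roi_m) + total_intensity(proj, roi_p)
        bg_mean = total_intensity(proj, cytoplasm_roi) / cytoplasm_roi.area_px
        corrected = total - area * bg_mean
        means[t] = corrected / area
        areas[t] = area
    return NuclearTimecourse(
        embryo_id=embryo_id,
        times_s=gfp_series.times_s(),
        mean_nuclear_value=means,
        roi_areas=areas,
    )


def pole_distance(
    p1: tuple[float, float], p2: tuple[float, float], pixel_size_um: float
) -> float:
    """Euclidean distance between two (x, y) points, in micrometres."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return float(np.hypot(p1[0] - p2[0], p1[1] - p2[1])) * pixel_size_um


def pole_distance_timecourse(
    pole_pairs: list[tuple[tuple[float, float], tuple[float, float]]],
    anaphase_frame: int,
    pixel_size_um: float,
    dt_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pole separation per frame, aligned so anaphase onset is t = 0."""
    if not 0 <= anaphase_frame < len(pole_pairs):
        raise ValueError("anaphase_frame outside the annotated range")
    d = np.array([pole_distance(a, b, pixel_size_um) for a, b in pole_pairs])
    times = (np.arange(len(pole_pairs)) - anaphase_frame) * dt_s
    return times, d


def neb_to_anaphase_interval(
    neb_frame: int, anaphase_frame: int, dt_s: float = 10.0
) -> float:
    """Mitotic timing: seconds from NEB to anaphase onset."""
    if anaphase_frame <= neb_frame:
        raise ValueError("anaphase onset must come after NEB")
    return (anaphase_frame - neb_frame) * dt_s


def _profile_of_frame(frame: np.ndarray, roi: Roi, orientation: str) -> np.ndarray:
    if roi.kind != "rect":
        raise ValueError("FRAP profiles require a rectangular ROI")
    if not roi.within(frame.shape):
        raise ValueError("FRAP ROI outside frame bounds")
    block = frame[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    if orientation == "horizontal":  # long axis along x: average the columns
        return block.mean(axis=0)
    if orientation == "vertical":
        return block.mean(axis=1)
    raise ValueError(f"orientation must be 'horizontal' or 'vertical', got {orientation!r}")


def frap_profiles(
    series: ImageSeries,
    roi: Roi,
    orientation: str = "horizontal",
    timepoint_labels: list[str] | None = None,
) -> list[FrapProfile]:
    """Average line profiles along a FRAP ROI, one per timepoint.

    The ROI (150x10 px in the original workflow, centred on the bleach
    border) is averaged across its short axis, giving one mean intensity
    per position along the long axis. Profiles are reported raw, with no
    normalization to pre-bleach levels.
    """
    labels = timepoint_labels or [f"t{t}" for t in range(len(series))]
    if len(labels) != len(series):
        raise ValueError("need one label per timepoint")
    out = []
    for t in range(len(series)):
        proj = max_project(series.stacks[t])
        vals = _profile_of_frame(proj, roi, orientation)
        out.append(FrapProfile(label=labels[t], positions=np.arange(vals.size), values=vals))
    return out


def average_profiles(replicates: list[FrapProfile]) -> FrapProfile:
    """Positionwise mean +- sample sd across biological replicates."""
    if not replicates:
        raise ValueError("no profiles to average")
    lengths = {p.values.size for p in replicates}
    if len(lengths) > 1:
        raise ValueError(f"replicate profiles differ in length: {sorted(lengths)}")
    stack = np.vstack([p.values for p in replicates])
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return FrapProfile(
        label=replicates[0].label,
        positions=replicates[0].positions.copy(),
        values=stack.mean(axis=0),
        sd=sd,
    )


def embryonic_lethality(
    records: "list[LethalityRecord] | pd.DataFrame",
) -> tuple[pd.DataFrame, float]:
    """Embryonic lethality per replicate and the condition mean.

    Lethality is (eggs laid - hatchlings) / eggs laid for each
    replicate; the condition summary is the plain mean of the replicate
    fractions (one data point per biological replicate). Accepts either
    records or a DataFrame with columns replicate_id / eggs_laid /
    hatchlings.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            LethalityRecord(str(r.replicate_id), int(r.eggs_laid), int(r.hatchlings))
            for r in records.itertuples()
        ]
    if not records:
        raise ValueError("no lethality records")
    df = pd.DataFrame(
        {
            "replicate_id": [r.replicate_id for r in records],
            "eggs_laid": [r.eggs_laid for r in records],
            "hatchlings": [r.hatchlings for r in records],
            "lethality_fraction": [r.lethality_fraction for r in records],
        }
    )
    return df, float(df["lethality_fraction"].mean())
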
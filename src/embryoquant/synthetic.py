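"""Seedable synthetic microscopy generators with recorded ground truth.

Each generator emulates one class of recording the quantification
stages consume — a condensing paternal pronucleus, a two-channel
metaphase plate of known foreground/background, a half-bleached plate
for FRAP, or plain measurement tables — and returns the images together
with a :class:`SceneGroundTruth` holding every true value a test may
compare against. Generators are pure functions of their parameters and
seed: the same seed reproduces bit-identical output.

Imaging model: expected photon counts are built geometrically
(uniform background, a disk of diffuse chromatin, Gaussian foci for
condensed chromosomes, rectangular plates), optionally blurred with an
isotropic Gaussian PSF, then corrupted with Poisson shot noise plus
additive Gaussian read noise and quantized to 16-bit counts. Frames
default to 256x256 (pass ``shape=(512, 512)`` for acquisition-scale
frames); the frame interval defaults to 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImageSeries, Roi, ZStack
from .metaphase import MetaphaseAnnotation
from .stats import GroupData

__all__ = [
    "NoiseModel",
    "SceneGroundTruth",
    "simulate_condensing_nucleus",
    "simulate_metaphase_plate",
    "simulate_metaphase_group",
    "simulate_frap_series",
    "simulate_measurement_groups",
]


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise on expected counts plus Gaussian read noise."""

    poisson: bool = True
    read_sd: float = 2.0


@dataclass
class SceneGroundTruth:
    """Everything true about a generated scene, recorded at generation time."""

    seed: int
    noise: NoiseModel | None
    centres: np.ndarray | None = None          # (T, 2) true pronucleus centre, (x, y)
    compaction: np.ndarray | None = None       # (T,) true compaction index in [0, 1]
    plate_foreground: float | None = None
    plate_background: float | None = None
    plate_area_px: int | None = None
    true_corrected_total: float | None = None  # area x (F - B)
    bleach_border_x: int | None = None
    bleach_depth: float | None = None
    recovery_rate: float | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, NoiseModel):
                return {"poisson": v.poisson, "read_sd": v.read_sd}
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}


def _acquire(expected: np.ndarray, rng: np.random.Generator, noise: NoiseModel | None) -> np.ndarray:
    """Turn an expected-count image into a 16-bit camera frame."""
    if noise is None:
        out = np.rint(expected)
    else:
        out = expected.astype(np.float64)
        if noise.poisson:
            out = rng.poisson(np.maximum(out, 0.0)).astype(np.float64)
        if noise.read_sd > 0:
            out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
        out = np.rint(out)
    return np.clip(out, 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# condensing pronucleus
# ---------------------------------------------------------------------------


def simulate_condensing_nucleus(
    n_frames: int = 40,
    neb_frame: int = 24,
    compaction_rate: float = 1.0 / 240.0,
    onset_frame: int = 0,
    dt_s: float = 10.0,
    shape: tuple[int, int] = (256, 256),
    n_slices: int = 5,
    seed: int = 0,
    noise: NoiseModel | None = NoiseModel(),
    nucleus_radius_px: float = 10.0,
    diffuse_amplitude: float = 120.0,
    focus_amplitude: float = 450.0,
    background: float = 20.0,
    n_foci: int = 6,
    psf_sigma_px: float = 1.0,
) -> tuple[ImageSeries, SceneGroundTruth]:
    """A time series of a pronucleus whose chromatin condenses into foci.

    The true compaction index ramps linearly from 0 starting at
    ``onset_frame``: ``c(t) = clip(compaction_rate * (t - onset_frame) *
    dt_s, 0, 1)``, so the default rate 1/240 s^-1 reaches full
    compaction 240 s after onset (at NEB with the default frames). As c
    rises the diffuse nucleoplasmic signal fades and ``n_foci`` Gaussian
    foci sharpen and brighten — the morphology the condensation
    parameter is designed to detect. ``compaction_rate = 0`` yields a
    static diffuse nucleus.

    The default nucleus radius (10 px, ~2 um at 0.2 um/px) makes the
    pronucleus comparable in size to the 21x21 analysis ROI, as in the
    recordings: the ROI then spans the nuclear rim, so its min-max
    rescale is anchored by real image structure rather than by noise
    extremes alone.
    """
    if n_frames < 1 or not 0 <= neb_frame < n_frames:
        raise ValueError("need n_frames >= 1 and 0 <= neb_frame < n_frames")
    if compaction_rate < 0:
        raise ValueError("compaction_rate must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    centre = np.array([w / 2.0, h / 2.0])
    drift = rng.normal(0.0, 0.3, size=(n_frames, 2)).cumsum(axis=0)
    centres = centre[None, :] + drift

    # foci positions fixed in the nucleus frame of reference
    ang = rng.uniform(0, 2 * np.pi, n_foci)
    rad = rng.uniform(2.0, 0.45 * nucleus_radius_px, n_foci)
    foci_offsets = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)

    t_idx = np.arange(n_frames)
    compaction = np.clip(compaction_rate * (t_idx - onset_frame) * dt_s, 0.0, 1.0)

    stacks = []
    mid = n_slices // 2
    for t in range(n_frames):
        c = compaction[t]
        cx, cy = centres[t]
        scene = np.full(shape, background, dtype=np.float64)
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_radius_px**2
        scene[disk] += diffuse_amplitude * (1.0 - 0.85 * c)
        if c > 0:
            sigma = 2.5 - 1.2 * c
            for ox, oy in foci_offsets:
                scene += (
                    focus_amplitude
                    * c
                    * np.exp(-(((xx - cx - ox) ** 2 + (yy - cy - oy) ** 2) / (2 * sigma**2)))
                )
        if psf_sigma_px > 0:
            scene = ndimage.gaussian_filter(scene, psf_sigma_px)
        slices = np.empty((n_slices, h, w), dtype=np.uint16)
        for z in range(n_slices):
            expected = scene if z == mid else np.full(shape, background)
            slices[z] = _acquire(expected, rng, noise)
        stacks.append(ZStack(slices))

    series = ImageSeries(stacks, dt_s=dt_s, channel="chromatin")
    truth = SceneGroundTruth(
        seed=seed,
        noise=noise,
        centres=centres,
        compaction=compaction,
        extras={"neb_frame": neb_frame, "onset_frame": onset_frame,
                "compaction_rate": compaction_rate},
    )
    return series, truth


# ---------------------------------------------------------------------------
# metaphase plates
# ---------------------------------------------------------------------------


def simulate_metaphase_plate(
    foreground: float = 2000.0,
    background: float = 200.0,
    plate_shape: tuple[int, int] = (8, 50),
    shape: tuple[int, int] = (256, 256),
    n_slices: int = 4,
    seed: int = 0,
    noise: NoiseModel | None = NoiseModel(),
    seg_foreground: float = 1000.0,
    seg_background: float = 50.0,
    embryo_id: str = "sim",
) -> tuple[ImageSeries, ImageSeries, MetaphaseAnnotation, SceneGroundTruth]:
    """A two-channel metaphase-plate recording of known intensities.

    The segmentation channel carries a bright rectangular plate for
    masking; the measurement channel carries expected intensity
    ``foreground`` on the plate and ``background`` elsewhere, with the
    plate signal confined to the middle z-slice so the sum projection's
    ring-corrected total equals ``area x (foreground - background)`` —
    recorded as :attr:`SceneGroundTruth.true_corrected_total`. With
    ``noise=None`` the recovery is exact.
    """
    if not foreground > background >= 0:
        raise ValueError("need foreground > background >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    ph, pw = plate_shape
    y0, x0 = (h - ph) // 2, (w - pw) // 2
    plate = np.zeros(shape, dtype=bool)
    plate[y0 : y0 + ph, x0 : x0 + pw] = True
    area = int(plate.sum())
    mid = n_slices // 2

    def make_series(bg: float, fg: float, label: str) -> ImageSeries:
        stacks = []
        for _t in range(2):  # metaphase frame + one post frame
            slices = np.empty((n_slices, h, w), dtype=np.uint16)
            for z in range(n_slices):
                expected = np.full(shape, bg, dtype=np.float64)
                if z == mid:
                    expected[plate] += fg - bg
                slices[z] = _acquire(expected, rng, noise)
            stacks.append(ZStack(slices))
        return ImageSeries(stacks, channel=label)

    seg = make_series(seg_background, seg_foreground, "chromatin")
    meas = make_series(background, foreground, "measurement")
    annotation = MetaphaseAnnotation(embryo_id=embryo_id, anaphase_onset_frame=1)
    truth = SceneGroundTruth(
        seed=seed,
        noise=noise,
        plate_foreground=foreground,
        plate_background=background,
        plate_area_px=area,
        true_corrected_total=area * (foreground - background),
        extras={"plate_roi": {"x0": x0, "y0": y0, "width": pw, "height": ph}},
    )
    return seg, meas, annotation, truth


def simulate_metaphase_group(
    n_embryos: int,
    foreground_scale: float = 1.0,
    seed: int = 0,
    base_foreground: float = 2000.0,
    background: float = 200.0,
    inter_embryo_cv: float = 0.08,
    noise: NoiseModel | None = NoiseModel(),
    **plate_kwargs,
) -> list[tuple[ImageSeries, ImageSeries, MetaphaseAnnotation, SceneGroundTruth]]:
    """A group of plate recordings with embryo-to-embryo intensity spread.

    ``foreground_scale`` scales the above-background plate signal (the
    tagged protein's contribution, what the ring correction measures):
    each embryo's plate foreground is ``background + signal_i`` with
    ``signal_i`` drawn around ``(base_foreground - background) *
    foreground_scale`` at coefficient of variation ``inter_embryo_cv``,
    emulating biological variability. A scale of 0.6 emulates a strain
    retaining ~60% of the wild-type chromatin-bound signal, so the
    normalized group mean recovers 0.6.
    """
    rng = np.random.default_rng(seed)
    out = []
    target_signal = (base_foreground - background) * foreground_scale
    for i in range(n_embryos):
        signal = rng.normal(target_signal, inter_embryo_cv * target_signal)
        f = background + max(signal, background * 0.1)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            simulate_metaphase_plate(
                foreground=f,
                background=background,
                seed=sub_seed,
                noise=noise,
                embryo_id=f"sim{i:03d}",
                **plate_kwargs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


def simulate_frap_series(
    pre_frames: int = 2,
    n_post: int = 10,
    bleach_depth: float = 0.8,
    recovery_rate: float = 0.0,
    dt_s: float = 1.5,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise: NoiseModel | None = NoiseModel(),
    plate_intensity: float = 1000.0,
    background: float = 50.0,
    plate_half_length: int = 88,
    plate_height: int = 10,
) -> tuple[ImageSeries, SceneGroundTruth, Roi]:
    """A half-bleached metaphase plate for FRAP line-profile analysis.

    The plate is a horizontal band; at the bleach event (after
    ``pre_frames`` frames) the left half drops to ``1 - bleach_depth``
    of its intensity and recovers exponentially with ``recovery_rate``
    (s^-1): ``factor(tau) = 1 - bleach_depth * exp(-recovery_rate *
    tau)``. Returns the series, the truth (border position, depth,
    rate), and the 150x10 analysis ROI centred on the bleach border.
    """
    if not 0 <= bleach_depth <= 1:
        raise ValueError("bleach_depth must be in [0, 1]")
    if recovery_rate < 0:
        raise ValueError("recovery_rate must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    border_x = w // 2
    y0 = (h - plate_height) // 2
    x_lo, x_hi = border_x - plate_half_length, border_x + plate_half_length

    n_frames = pre_frames + n_post
    stacks = []
    for t in range(n_frames):
        expected = np.full(shape, background, dtype=np.float64)
        band = (slice(y0, y0 + plate_height), slice(x_lo, x_hi))
        expected[band] = plate_intensity
        if t >= pre_frames:
            tau = (t - pre_frames) * dt_s
            factor = 1.0 - bleach_depth * np.exp(-recovery_rate * tau)
            expected[y0 : y0 + plate_height, x_lo:border_x] = (
                background + (plate_intensity - background) * factor
            )
        stacks.append(ZStack(_acquire(expected, rng, noise)[None]))

    series = ImageSeries(stacks, dt_s=dt_s, channel="frap")
    roi = Roi.rectangle(border_x - 75, y0, 150, plate_height)
    truth = SceneGroundTruth(
        seed=seed,
        noise=noise,
        bleach_border_x=border_x,
        bleach_depth=bleach_depth,
        recovery_rate=recovery_rate,
        extras={"pre_frames": pre_frames, "plate_intensity": plate_intensity,
                "background": background},
    )
    return series, truth, roi


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def simulate_measurement_groups(
    group_means,
    sds,
    ns,
    distribution: str = "normal",
    seed: int = 0,
    labels: list[str] | None = None,
) -> list[GroupData]:
    """Draw per-group measurement tables for statistics calibration.

    ``distribution="normal"`` draws Gaussian samples;
    ``"lognormal"`` draws right-skewed lognormal samples matched to the
    requested mean and sd (to exercise the non-parametric branch).
    """
    group_means = np.atleast_1d(np.asarray(group_means, dtype=np.float64))
    sds = np.atleast_1d(np.asarray(sds, dtype=np.float64))
    ns = np.atleast_1d(np.asarray(ns, dtype=np.int64))
    if not (len(group_means) == len(sds) == len(ns)):
        raise ValueError("group_means, sds and ns must have equal length")
    if labels is None:
        labels = [f"group{i}" for i in range(len(ns))]
    rng = np.random.default_rng(seed)
    out = []
    for label, m, s, n in zip(labels, group_means, sds, ns):
        if distribution == "normal":
            vals = rng.normal(m, s, int(n))
        elif distribution == "lognormal":
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            vals = rng.lognormal(mu, np.sqrt(sigma2), int(n))
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        out.append(GroupData(label=label, values=vals, is_control=label == labels[0]))
    return out
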
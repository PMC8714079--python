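# Methods

This note documents the models, conventions and parameter choices
behind each pipeline, the assumptions of the synthetic-data generators,
and the numerical decisions made where the original workflows leave
details open.

## Image model and geometry

Frames are 2-D arrays of non-negative, unitless camera counts (8- or
16-bit typical; bit depth is not assumed beyond non-negativity). A
timepoint is a z-stack of identically shaped slices; a series carries
the frame interval `dt_s` (default 10 s, the acquisition cadence of the
recordings modelled here) and the lateral pixel size in µm. Coordinates
are 0-based with `(x, y)` point order and half-open rectangles
`[x0, x0+w) × [y0, y0+h)`. Sum projections accumulate in int64/float64
and are never clipped to the input bit depth. Channels are assumed
registered (simultaneous two-channel acquisition); no registration,
drift correction, deconvolution or flat-fielding is provided. Z-drift
during acquisition is ignored: stacks are treated as complete per
timepoint.

## Auto-thresholding

Both threshold operators work on a 256-bin histogram spanning the
data's min–max range — the 8-bit convention of the Fiji functions they
reproduce — and are exact exhaustive maximizations of their criterion
over every candidate split:

* **Otsu**: maximize `w0·w1·(μ0−μ1)²` over bin indices.
* **Maximum entropy** (Kapur–Sahoo–Wong): maximize the sum of Shannon
  entropies of the renormalized background and foreground
  distributions. Only splits leaving both classes non-empty are
  candidates; a degenerate split would trivially score the total
  entropy, and the restriction matches the reference tool.

Integer data whose range fits in 256 bins gets unit-width integer-level
bins (bin = level), so thresholds on 8-bit data are integer levels;
wider data is binned over [min, max] and the split is mapped back to a
raw intensity. Foreground is strictly greater than the threshold level.
Ties — including the exact mathematical ties produced by symmetric or
sparse histograms — break to the smallest level; because float
evaluation order can split an exact tie, the argmax is taken as the
smallest split within a 1e-10 relative tolerance of the maximum.
Constant images raise rather than threshold.

A min–max contrast stretch (monotone, rank-preserving) and a circular
mean filter (radius 2 px, edge handling by averaging in-bounds
neighbours only) prepare segmentation copies of frames; quantified
pixels are never filtered or stretched. Connected components use
8-connectivity (the reference tool's particle-analysis default), and
"expand by k px in each direction" is Chebyshev (square) dilation
clipped to the image.

## Metaphase-plate quantification

The metaphase frame is `anaphase_onset − 1`. Segmentation runs on the
chromatin channel's max projection (max-entropy threshold → largest
component, or the component nearest an annotated seed); measurement
runs on the measurement channel's sum projection; single-marker strains
use one channel for both. The background ring is the set difference
between the 5-px-dilated ROI and the plate ROI, applied on the dilated
mask (not a bounding box). The correction `T − A·(T_e−T)/(A_e−A)`
cancels any global additive offset exactly when the ring is pure
background. Negative corrected totals are reported as-is and flagged;
clipping them would bias group means. Normalization divides by the
control mean, so the control group averages exactly 1.

## Condensation parameter

Configuration: 21×21 px square ROI (odd, so it can be centred),
rescale maximum 255, threshold fraction 0.4 → cut-off 102, loess span
0.4. Rescaled values are kept as reals (no re-binning, which would only
add quantization error), and "below threshold" is the strict inequality
`< 102`; a boundary pixel at exactly 102 counts as not-below. A
constant ROI returns 0.0 — uniform nucleoplasm shows no visible
condensation, the statistic's diffuse limit. The parameter equals the
empirical CDF of the rescaled values at the cut-off, hence is invariant
under any positive affine transform of the raw pixels.

Per timepoint the pronucleus is centred on a filtered segmentation copy
(contrast stretch → mean filter r=2 → Otsu → centroid of the component
nearest the tracking seed, rounded to the nearest pixel); the previous
frame's centre seeds the next frame, so the ROI tracks the nucleus. The
parameter itself is always computed on the raw, unfiltered max
projection: filtering would alter the very pixel distribution the
statistic summarizes, and the min–max rescale already removes gain and
offset effects. If centring fails on a frame the previous centre is
carried forward for at most 2 consecutive frames (logged); longer
losses raise. ROIs are clipped at the frame border.

Curves are aligned to NEB (t = 0, negative before) on a common `dt`
grid; aggregation reports per-timepoint mean, sample sd (ddof 1; 0 with
a flag when only one embryo contributes) and n. Display smoothing is
loess: for each point, a degree-1 weighted least-squares fit over the
`⌈span·n⌉` nearest points with tricube weights `(1−(d/d_max)³)³`,
exact on linear data by construction; windows of fewer than 3 points
raise (aggregation falls back to the unsmoothed mean for very short
curves).

## Other time-course metrics

Nuclear time courses use max projections (z-stacks do not reliably
cover both pronuclei, so sums would understate volume): corrected
mean = [(T_maternal + T_paternal) − (A_m + A_p)·mean(cytoplasm ROI)] /
(A_m + A_p), with a manually annotated 25×25 px cytoplasm region and
non-overlapping nuclear ROIs. Pole distances are Euclidean distances of
annotated (possibly fractional) coordinates times the pixel size,
aligned so anaphase onset is t = 0. The mitotic interval is
`(anaphase − NEB)·dt`. FRAP analysis averages a 150×10 px ROI across
its short axis per timepoint and averages replicate profiles
positionwise (mean ± sample sd); profiles are reported raw, with no
pre-bleach normalization and no kinetic model fit (the recordings being
emulated show no recovery). Embryonic lethality is
(laid − hatched)/laid per replicate; the condition summary is the plain
mean over replicates.

## Statistical decision tree

Significance level α = 0.05 throughout. Each group (n ≥ 3) is screened
with Shapiro–Wilk; a group is treated as normal when p ≥ 0.05. All
groups normal: two groups use Student's t when the sample-variance
ratio max(s²)/min(s²) < 3 and Welch's t otherwise; more than two groups
use one-way ANOVA with a Tukey–Kramer post hoc (studentized-range
distribution, valid for unequal n). Any non-normal group switches the
whole comparison to Kruskal–Wallis with Dunn's rank-based z post hoc
(tie-corrected) and Benjamini–Hochberg adjustment across pairs.
Variance similarity is judged on the same normalized values fed to the
test. Tukey–Kramer p-values are inherently family-adjusted and are
reported in both the raw and adjusted columns; two-sample branches need
no adjustment. The plan object records every input to the decision
(per-group SW p, variance ratio, group count), making the tree a pure,
auditable function of those inputs.

## Synthetic data

Generators are pure functions of their parameters and seed (bit-identical
reruns). Imaging model: expected photon counts built geometrically,
blurred by an isotropic Gaussian PSF where stated, then Poisson shot
noise plus additive Gaussian read noise (sd 2 counts), quantized to
uint16. Frames default to 256×256 for desk-scale runs (512×512
available via `shape=`); `dt` defaults to 10 s.

* **Condensing nucleus**: a disk-shaped pronucleus (radius 10 px — the
  pronucleus is comparable in size to the 21×21 analysis ROI, so the
  ROI spans the nuclear rim and its min–max rescale is anchored by real
  structure rather than noise extremes) with diffuse amplitude 120 over
  background 20, drifting by a small random walk (truth-recorded). The
  true compaction index ramps linearly at `compaction_rate` (default
  1/240 s⁻¹, i.e. full compaction 240 s after onset); as it rises, six
  Gaussian foci brighten (to 450) and sharpen (σ 2.5→1.3 px) while the
  diffuse signal fades by 85%. Signal lives in the middle of 5 z-slices.
* **Metaphase plate**: rectangular plate (default 8×50 px = 400 px) in
  the middle z-slice of 4; the measurement channel carries expected
  F = 2000 on the plate over B = 200 elsewhere, so the ring-corrected
  sum-projection total has ground truth A·(F−B); noise-free mode is
  exact by construction. Group generation scales the above-background
  signal (the tagged protein's contribution) per embryo with 8%
  coefficient of variation, so a 0.6 scale yields a normalized group
  mean of 0.6.
* **FRAP**: a horizontal plate band whose left half drops to
  `1 − depth` at the bleach frame and recovers as
  `1 − depth·e^(−rate·τ)`; the border position and the 150×10 analysis
  ROI centred on it are returned with the truth.
* **Measurement tables**: Gaussian or moment-matched lognormal draws
  per group, for calibrating the decision tree.

What the generators do *not* emulate: chromosome mechanics, 3-D PSFs,
spectral bleed-through, autofluorescence gradients, stage drift beyond
the nuclear random walk, or z-dependent signal. Passing tests therefore
demonstrate the correctness and calibration of the measurement code
under a standard camera-noise model, not performance on real
microscopy; segmentation robustness on real data still depends on
acquisition quality.

## Problem sizes and runtime

The default test and acceptance runs use 256×256 frames, 20–40-frame
series, 1000-histogram threshold sweeps, 1000-ROI invariance sweeps,
20 embryos per simulated group, 1000-rep power and 2000-rep type-I
calibrations, and 10 paired seeds for the rate-ordering check; the full
suite runs in under a minute on one CPU, the acceptance script in about
half a minute.

## Known limitations

* NEB and anaphase onset are annotations, not detected events.
* The condensation-centred ROI tracking assumes the pronucleus moves
  less than its diameter between frames (10-s cadence makes this safe).
* Thresholds computed on 256-bin histograms of 16-bit data quantize the
  threshold to 1/256 of the data range, faithfully to the reference
  tool but coarser than a full 16-bit search.
* Dunn's post hoc uses the large-sample normal approximation (standard);
  very small groups in the non-parametric branch get approximate p-values.
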
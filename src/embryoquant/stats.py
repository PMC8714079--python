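"""Statistical decision tree and post-hoc machinery for group comparisons.

Normalized intensity measurements are compared between strains with the
following tree (significance level alpha = 0.05 throughout):

* every group is screened with a Shapiro-Wilk normality test;
* if all groups look normal (each p >= 0.05):
    - two groups with similar variances (max/min sample-variance ratio
      < 3) -> two-tailed unpaired Student's t-test;
    - two groups with a >= 3-fold variance difference -> Welch's t-test;
    - more than two groups -> one-way ANOVA followed by a Tukey-Kramer
      post hoc (studentized-range distribution, valid for unequal n);
* if any group is non-normal -> Kruskal-Wallis followed by Dunn's post
  hoc with Benjamini-Hochberg adjustment of the pairwise p-values.

The tree is a pure function of the Shapiro-Wilk p-values, the variance
ratio and the group count; :func:`choose_test` records all three in the
returned plan so every decision is auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "TestPlan",
    "PairResult",
    "ComparisonResult",
    "ALPHA",
    "assess_normality",
    "choose_test",
    "run_comparison",
    "benjamini_hochberg",
]

ALPHA = 0.05
VARIANCE_RATIO_CUTOFF = 3.0


@dataclass
class GroupData:
    """One condition's normalized measurements."""

    label: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("group values must be 1-D")


@dataclass
class TestPlan:
    """The chosen test plus every input to the decision."""

    test: str  # student_t | welch_t | anova_tukey_kramer | kruskal_dunn_bh
    normality_p: dict[str, float]
    variance_ratio: float
    rationale: str
    alpha: float = ALPHA


@dataclass
class PairResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonResult:
    test: str
    pairs: list[PairResult]
    overall_statistic: float | None = None
    overall_p: float | None = None
    plan: TestPlan | None = field(default=None, repr=False)


def assess_normality(values) -> float:
    """Shapiro-Wilk p-value for one sample (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 values")
    if values.size > 5000:
        raise ValueError("Shapiro-Wilk p-values unreliable above n = 5000")
    return float(sps.shapiro(values).pvalue)


def choose_test(groups: list[GroupData], alpha: float = ALPHA) -> TestPlan:
    """Apply the decision tree and return the plan with its inputs."""
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g in groups:
        if g.values.size < 3:
            raise ValueError(f"group {g.label!r} has n < 3")

    normality_p = {g.label: assess_normality(g.values) for g in groups}
    variances = np.array([np.var(g.values, ddof=1) for g in groups])
    vmin = variances.min()
    ratio = float(variances.max() / vmin) if vmin > 0 else np.inf

    all_normal = all(p >= alpha for p in normality_p.values())
    if not all_normal:
        worst = min(normality_p, key=normality_p.get)
        test = "kruskal_dunn_bh"
        why = (
            f"group {worst!r} failed Shapiro-Wilk (p = {normality_p[worst]:.3g} < "
            f"{alpha}); non-parametric branch"
        )
    elif len(groups) == 2:
        if ratio < VARIANCE_RATIO_CUTOFF:
            test = "student_t"
            why = f"2 normal groups, variance ratio {ratio:.2f} < {VARIANCE_RATIO_CUTOFF}"
        else:
            test = "welch_t"
            why = f"2 normal groups, variance ratio {ratio:.2f} >= {VARIANCE_RATIO_CUTOFF}"
    else:
        test = "anova_tukey_kramer"
        why = f"{len(groups)} normal groups; one-way ANOVA with Tukey-Kramer post hoc"
    return TestPlan(
        test=test, normality_p=normality_p, variance_ratio=ratio, rationale=why, alpha=alpha
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(sps.false_discovery_control(p, method="bh"))


def _dunn_pairs(groups: list[GroupData]) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based pairwise z tests with tie correction (raw p)."""
    pooled = np.concatenate([g.values for g in groups])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, ns = {}, {}
    start = 0
    for g in groups:
        n = g.values.size
        mean_ranks[g.label] = ranks[start : start + n].mean()
        ns[g.label] = n
        start += n
    # tie correction: sum over tie groups of (t^3 - t)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    out = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / ns[a.label] + 1.0 / ns[b.label]))
        z = (mean_ranks[a.label] - mean_ranks[b.label]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((a.label, b.label, float(z), float(min(p, 1.0))))
    return out


def run_comparison(
    groups: list[GroupData], plan: TestPlan | None = None, alpha: float = ALPHA
) -> ComparisonResult:
    """Execute the planned test and report per-pair raw/adjusted p-values.

    With ``plan=None`` the decision tree is applied first. For the two-
    sample branches the single pair needs no multiplicity adjustment
    (adjusted = raw). Tukey-Kramer p-values come from the studentized-
    range distribution and are inherently family-adjusted; they are
    reported in both columns. Dunn's pairwise p-values are adjusted with
    Benjamini-Hochberg across all pairs.
    """
    if plan is None:
        plan = choose_test(groups, alpha=alpha)
    pooled = np.concatenate([g.values for g in groups])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate data: all values identical in all groups")

    labels = [g.label for g in groups]
    values = [g.values for g in groups]
    pairs: list[PairResult] = []
    overall_stat = overall_p = None

    if plan.test in ("student_t", "welch_t"):
        if len(groups) != 2:
            raise ValueError(f"{plan.test} requires exactly 2 groups")
        res = sps.ttest_ind(values[0], values[1], equal_var=plan.test == "student_t")
        pairs.append(
            PairResult(
                labels[0], labels[1], float(res.statistic), float(res.pvalue),
                float(res.pvalue), bool(res.pvalue < alpha),
            )
        )
        overall_stat, overall_p = float(res.statistic), float(res.pvalue)
    elif plan.test == "anova_tukey_kramer":
        f = sps.f_oneway(*values)
        overall_stat, overall_p = float(f.statistic), float(f.pvalue)
        tk = sps.tukey_hsd(*values)
        for i, j in itertools.combinations(range(len(groups)), 2):
            p = float(tk.pvalue[i, j])
            pairs.append(
                PairResult(labels[i], labels[j], float(tk.statistic[i, j]), p, p, p < alpha)
            )
    elif plan.test == "kruskal_dunn_bh":
        kw = sps.kruskal(*values)
        overall_stat, overall_p = float(kw.statistic), float(kw.pvalue)
        raw = _dunn_pairs(groups)
        adj = benjamini_hochberg([r[3] for r in raw])
        for (a, b, z, p_raw), p_adj in zip(raw, adj):
            pairs.append(PairResult(a, b, z, p_raw, float(p_adj), bool(p_adj < alpha)))
    else:
        raise ValueError(f"unknown test {plan.test!r}")

    return ComparisonResult(
        test=plan.test,
        pairs=pairs,
        overall_statistic=overall_stat,
        overall_p=overall_p,
        plan=plan,
    )
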
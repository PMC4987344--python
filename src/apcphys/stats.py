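"""Group-comparison test selection and execution.

The selection policy is the one used throughout the study's analyses:

==============================  =========================================
design                          test
==============================  =========================================
2 groups, min n < 10, unpaired  Mann-Whitney U (MWU)
2 groups, min n < 10, paired    Wilcoxon signed ranks (WSR)
2 groups, n >= 10, eq. var      Student's t (paired t when paired)
2 groups, n >= 10, uneq. var    Welch's t
> 2 groups, equal variances     one-way ANOVA with post-hoc Tukey
> 2 groups, unequal variances,
  equal sizes                   Welch's ANOVA
> 2 groups, unequal variances
  and unequal sizes             Kruskal-Wallis (KW)
==============================  =========================================

Variance homogeneity is assessed with Levene's test at alpha = 0.05.  Tests
are two-sided unless a directional hypothesis is configured.  Exact
small-sample p-values are used for MWU/WSR when there are no ties.
Summaries report the mean +/- SE, and medians with quartiles (Q1, Q3,
linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonDesign",
    "TestResult",
    "GroupSummary",
    "design_from_data",
    "select_test",
    "run_test",
    "summarize_group",
    "LEVENE_ALPHA",
    "SMALL_N",
]

LEVENE_ALPHA = 0.05
SMALL_N = 10


@dataclass(frozen=True)
class ComparisonDesign:
    """The facts about a comparison that determine which test applies."""

    n_groups: int
    sizes: tuple[int, ...]
    paired: bool = False
    equal_variance: bool = True

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least two groups")
        if len(self.sizes) != self.n_groups:
            raise ValueError("one size per group required")
        if any(s < 1 for s in self.sizes):
            raise ValueError("group sizes must be >= 1")
        if self.paired and len(set(self.sizes)) != 1:
            raise ValueError("paired designs require equal group sizes")

    @property
    def equal_sizes(self) -> bool:
        return len(set(self.sizes)) == 1

    @property
    def small(self) -> bool:
        return min(self.sizes) < SMALL_N


def design_from_data(
    groups: Sequence[np.ndarray], paired: bool = False
) -> ComparisonDesign:
    """Build a design from raw data, assessing variance homogeneity (Levene)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if all(len(g) > 1 for g in groups) and any(np.std(g) > 0 for g in groups):
        _, p = sps.levene(*groups)
        equal_var = bool(p >= LEVENE_ALPHA)
    else:
        equal_var = True
    return ComparisonDesign(
        n_groups=len(groups),
        sizes=tuple(len(g) for g in groups),
        paired=paired,
        equal_variance=equal_var,
    )


def select_test(design: ComparisonDesign) -> str:
    """Deterministic test name for a comparison design (table above)."""
    if design.n_groups == 2:
        if design.small:
            return "WSR" if design.paired else "MWU"
        if design.paired:
            return "paired-t"
        return "t" if design.equal_variance else "Welch-t"
    if design.paired:
        raise ValueError("paired designs with more than two groups unsupported")
    if design.equal_variance:
        return "ANOVA-Tukey"
    return "ANOVA-Welch" if design.equal_sizes else "KW"


@dataclass
class GroupSummary:
    """mean +/- SE and median with quartiles for one group."""

    n: int
    mean: float
    se: float
    median: float
    q1: float
    q3: float
    notes: list[str] = field(default_factory=list)


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Summary statistics under the documented conventions.

    Quartiles use linear interpolation; SE uses the sample (n-1) SD and is
    flagged undefined (NaN) for a single observation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    notes = []
    if v.size == 1:
        se = float("nan")
        notes.append("SE undefined for n=1")
    else:
        se = float(np.std(v, ddof=1) / np.sqrt(v.size))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        n=int(v.size), mean=float(v.mean()), se=se,
        median=float(med), q1=float(q1), q3=float(q3), notes=notes,
    )


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    summaries: list[GroupSummary] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _has_ties(*arrays: np.ndarray) -> bool:
    pooled = np.concatenate(arrays)
    return len(np.unique(pooled)) < len(pooled)


def run_test(
    name: str,
    groups: Sequence[Sequence[float]],
    alternative: str = "two-sided",
) -> TestResult:
    """Run a named test on the given groups.

    MWU and WSR use exact permutation distributions for small samples
    without ties (scipy's exact mode); degenerate inputs (all-tied WSR
    differences, zero variance) are reported in ``notes`` rather than
    silently dropped.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    notes: list[str] = []
    extra: dict[str, Any] = {}

    if name == "MWU":
        if len(gs) != 2:
            raise ValueError("MWU needs exactly two groups")
        method = "exact" if (max(map(len, gs)) <= 25 and not _has_ties(*gs)) else "auto"
        res = sps.mannwhitneyu(gs[0], gs[1], alternative=alternative, method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        if _has_ties(*gs):
            notes.append("ties present; normal approximation used")
    elif name == "WSR":
        if len(gs) != 2 or len(gs[0]) != len(gs[1]):
            raise ValueError("WSR needs two paired groups of equal size")
        diff = gs[0] - gs[1]
        if np.all(diff == 0):
            return TestResult(
                test=name, statistic=0.0, p_value=1.0,
                summaries=[summarize_group(g) for g in gs],
                notes=["all paired differences are zero"],
            )
        if np.any(diff == 0):
            notes.append("zero differences present (zsplit handling)")
        method = (
            "exact" if (len(diff) <= 25 and not _has_ties(np.abs(diff))
                        and not np.any(diff == 0)) else "auto"
        )
        res = sps.wilcoxon(
            gs[0], gs[1], alternative=alternative, method=method,
            zero_method="zsplit",
        )
        stat, p = float(res.statistic), float(res.pvalue)
    elif name in ("t", "Welch-t"):
        res = sps.ttest_ind(gs[0], gs[1], equal_var=(name == "t"),
                            alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    elif name == "paired-t":
        res = sps.ttest_rel(gs[0], gs[1], alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    elif name == "ANOVA-Tukey":
        res = sps.f_oneway(*gs)
        stat, p = float(res.statistic), float(res.pvalue)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(gs)
        labels = np.concatenate(
            [np.full(len(g), i) for i, g in enumerate(gs)]
        )
        tukey = pairwise_tukeyhsd(values, labels)
        extra["tukey"] = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
    elif name == "ANOVA-Welch":
        import pingouin as pg

        df = pd.DataFrame(
            {
                "value": np.concatenate(gs),
                "group": np.concatenate(
                    [np.full(len(g), i) for i, g in enumerate(gs)]
                ),
            }
        )
        aov = pg.welch_anova(data=df, dv="value", between="group")
        p_col = "p-unc" if "p-unc" in aov.columns else "p_unc"
        stat, p = float(aov["F"].iloc[0]), float(aov[p_col].iloc[0])
    elif name == "KW":
        res = sps.kruskal(*gs)
        stat, p = float(res.statistic), float(res.pvalue)
    elif name == "pearson":
        if len(gs) != 2 or len(gs[0]) != len(gs[1]):
            raise ValueError("pearson needs two paired variables")
        res = sps.pearsonr(gs[0], gs[1], alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {name!r}")

    if any(len(g) > 1 and np.std(g, ddof=1) == 0 for g in gs):
        notes.append("zero-variance group present")
    return TestResult(
        test=name, statistic=stat, p_value=p,
        summaries=[summarize_group(g) for g in gs],
        extra=extra, notes=notes,
    )
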
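"""Group-comparison statistics shared by all pipeline stages.

Implements the tests used throughout the workflow: two-tailed two-sample
Student and Welch t-tests, the Mann-Whitney U test, one-way ANOVA, and the
Benjamini-Hochberg step-up FDR adjustment. Summaries are reported as
mean +/- standard error with sample (n-1) standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupSummary:
    n: int
    mean: float
    se: Optional[float]


@dataclass
class GroupComparison:
    test_name: str  # student_t | welch_t | mann_whitney | anova_oneway
    statistic: float
    p_value: float
    groups: List[GroupSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")


def mean_se(values: Sequence[float]):
    """Mean and standard error (sample SD / sqrt(n)).

    n = 1 gives ``(mean, None)``; the caller decides how to display an
    undefined SE.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mean_se requires at least one value")
    mean = float(x.mean())
    if x.size == 1:
        return mean, None
    se = float(x.std(ddof=1) / math.sqrt(x.size))
    return mean, se


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed summary
    tables, as opposed to banker's rounding)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _summaries(*samples) -> List[GroupSummary]:
    out = []
    for s in samples:
        m, se = mean_se(s)
        out.append(GroupSummary(n=len(s), mean=m, se=se))
    return out


def two_sample_t(x, y, welch: bool = False) -> GroupComparison:
    """Two-tailed two-sample t-test; pooled variance or Welch-corrected."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("two_sample_t requires n >= 2 per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        # degenerate: no within-group variability
        stat, p = (0.0, 1.0) if x.mean() == y.mean() else (math.inf, 0.0)
    else:
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
    return GroupComparison(
        test_name="welch_t" if welch else "student_t",
        statistic=float(stat),
        p_value=float(p),
        groups=_summaries(x, y),
    )


def mann_whitney(x, y, method: str = "auto") -> GroupComparison:
    """Mann-Whitney U with midrank ties.

    ``method='auto'`` uses the exact null distribution when the smaller
    sample has at most 8 observations and there are no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney requires n >= 1 per group")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=_summaries(x, y),
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """One-way ANOVA: F = MS_between / MS_within.

    Zero within-group variance is handled explicitly: equal means give
    F = 0 (p = 1), separated means give F = inf (p = 0).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("anova_oneway requires >= 2 groups with n >= 2 each")
    k = len(gs)
    n_tot = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_tot - k
    # sums of squares that are zero up to float cancellation count as zero
    scale = max(1.0, float(np.abs(np.concatenate(gs)).max()))
    tol = n_tot * (1e-9 * scale) ** 2
    if ss_within <= tol:
        stat, p = (0.0, 1.0) if ss_between <= tol else (math.inf, 0.0)
    else:
        stat = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(stat, df1, df2))
    return GroupComparison(
        test_name="anova_oneway",
        statistic=float(stat),
        p_value=float(p),
        groups=_summaries(*gs),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
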
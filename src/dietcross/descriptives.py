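"""Group-comparison statistics and broad-sense heritability.

Welch and pooled two-sample t-tests accept either raw values or printed
(mean, SD, n) summaries, so published group summaries can be re-analyzed
directly.  The Wilcoxon rank-sum test reports an exact p-value for small
tie-free samples and a tie-corrected normal approximation otherwise,
together with the Hodges–Lehmann shift estimate and its distribution-free
confidence interval.  Broad-sense heritability is estimated from the
excess of F2 phenotypic variance over F1 (environmental) variance:
H² = (V_F2 − V_F1)/V_F2, truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import scipy.stats

__all__ = ["GroupSummary", "ComparisonResult", "welch_t", "student_t",
           "wilcoxon_rank_sum", "fold_change", "broad_sense_heritability"]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-summary form of a group: label, n, mean, SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("sd must be finite and non-negative")


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group comparison: estimate, CI, statistic, df, p, method."""

    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    df: float
    p: float
    method: str
    level: float = 0.95


def _as_summary(g, label: str) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    x = np.asarray(g, dtype=float)
    x = x[np.isfinite(x)]
    return GroupSummary(label, len(x), float(x.mean()), float(x.std(ddof=1)))


def welch_t(g1, g2, level: float = 0.95) -> ComparisonResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a, b = _as_summary(g1, "g1"), _as_summary(g2, "g2")
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    diff = a.mean - b.mean
    se = np.sqrt(va + vb)
    if se == 0:
        raise ValueError("zero variance in both groups: test undefined")
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = diff / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    crit = scipy.stats.t.ppf(0.5 + level / 2.0, df)
    return ComparisonResult(diff, diff - crit * se, diff + crit * se, t, float(df),
                            float(p), "welch", level)


def student_t(g1, g2, level: float = 0.95) -> ComparisonResult:
    """Pooled-variance two-sample t-test."""
    a, b = _as_summary(g1, "g1"), _as_summary(g2, "g2")
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    diff = a.mean - b.mean
    if se == 0:
        raise ValueError("zero pooled variance: test undefined")
    t = diff / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    crit = scipy.stats.t.ppf(0.5 + level / 2.0, df)
    return ComparisonResult(diff, diff - crit * se, diff + crit * se, t, float(df),
                            float(p), "student", level)


def wilcoxon_rank_sum(x, y, level: float = 0.95) -> ComparisonResult:
    """Wilcoxon/Mann–Whitney rank-sum test with a Hodges–Lehmann CI.

    Exact p for min(n) ≤ 8 without ties; otherwise a tie-corrected normal
    approximation with continuity correction.  The estimate is the median
    of all pairwise differences x − y; its CI is the distribution-free
    interval from the Mann–Whitney count statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least 1 observation")
    pooled = np.concatenate([x, y])
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    n1, n2 = len(x), len(y)
    if np.unique(pooled).size == pooled.size and min(n1, n2) <= 8:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif np.unique(pooled).size == 1:
        res = None
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                       use_continuity=True)
    u = float(res.statistic) if res is not None else n1 * n2 / 2.0
    p = float(res.pvalue) if res is not None else 1.0
    # distribution-free CI bounds from the normal approximation to U
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    k = int(np.floor(n1 * n2 / 2.0 - z * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    lo = diffs[k] if k < len(diffs) else diffs[0]
    hi = diffs[len(diffs) - 1 - k]
    return ComparisonResult(hl, float(lo), float(hi), u, np.nan, p, "wilcoxon", level)


def fold_change(mean_num: float, mean_den: float, decimals: int = 2) -> float:
    """Ratio of group means, rounded to the report convention (2 decimals)."""
    if mean_den == 0:
        raise ZeroDivisionError("fold change undefined for zero denominator")
    return round(mean_num / mean_den, decimals)


def broad_sense_heritability(
    var_f2: float, var_f1: float, literal_ratio: bool = False
) -> float:
    """Broad-sense heritability from F2 and F1 phenotypic variances.

    The F2 variance contains genetic plus environmental variance; the F1
    cohort is genetically uniform, so its variance is environmental.  The
    default estimator is H² = (V_F2 − V_F1)/V_F2 truncated to [0, 1].
    ``literal_ratio`` returns V_F2/V_F1 instead (a variance ratio that can
    exceed 1, provided for comparison).
    """
    if var_f2 < 0 or var_f1 < 0:
        raise ValueError("variances must be non-negative")
    if var_f2 == 0:
        raise ValueError("H2 undefined for zero F2 variance")
    if literal_ratio:
        return var_f2 / var_f1 if var_f1 > 0 else np.inf
    return float(np.clip((var_f2 - var_f1) / var_f2, 0.0, 1.0))
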
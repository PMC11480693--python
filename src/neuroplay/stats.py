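"""Feature-target correlation analytics and group comparisons.

Test selection follows the distribution of the data: Pearson correlation,
t tests and one-way ANOVA when every sample passes a Shapiro-Wilk
normality check at alpha = 0.05, otherwise their rank-based counterparts
(Spearman, Mann-Whitney U, Kruskal-Wallis); chi-square for contingency
tables.  Pairwise multiplicity is controlled with the Holm-Bonferroni
step-down procedure.  Missing values are removed pairwise before
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError

NORMALITY_ALPHA = 0.05
MODERATE_R = 0.4
SIG_ALPHA = 0.05


def is_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """Shapiro-Wilk gate; vectors too short to test are treated as
    non-normal (rank tests are the safe default)."""
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


@dataclass(frozen=True)
class CorrelationResult:
    feature_id: str
    target: str
    method: str  # 'pearson' | 'spearman'
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    adjusted_r2: float


@dataclass(frozen=True)
class GroupComparison:
    feature_id: str
    groups: tuple
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None


def correlate(x, y, feature_id: str = "", target: str = "") -> CorrelationResult:
    """Correlation plus simple linear regression after pairwise deletion.

    The correlation method is Pearson when both vectors pass the normality
    gate, Spearman otherwise.  The slope/intercept and the adjusted R^2 =
    1 - (1 - r^2)(n - 1)/(n - 2) come from the ordinary least-squares line
    regardless of the correlation method reported.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    if is_normal(x) and is_normal(y):
        method = "pearson"
        r, p = sps.pearsonr(x, y)
    else:
        method = "spearman"
        r, p = sps.spearmanr(x, y)
    fit = sps.linregress(x, y)
    r2 = fit.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrelationResult(feature_id, target, method, float(r), float(p),
                             n, float(fit.slope), float(fit.intercept),
                             float(adj))


def select_moderate(results, r_threshold: float = MODERATE_R,
                    alpha: float = SIG_ALPHA):
    """Moderate correlations: |R| strictly above the threshold and
    significant."""
    return [c for c in results
            if abs(c.r) > r_threshold and c.p_value < alpha]


def compare_groups(values, labels, feature_id: str = "",
                   categorical: bool = False) -> GroupComparison:
    """Two numeric groups -> t test (both normal) or Mann-Whitney U; more
    than two -> one-way ANOVA (all normal) or Kruskal-Wallis H; categorical
    data (a contingency table) -> chi-square."""
    if categorical:
        table = np.asarray(values, float)
        if table.ndim != 2 or min(table.shape) < 2:
            raise DegenerateInputError("need a 2-D contingency table")
        chi2 = sps.chi2_contingency(table, correction=False)
        return GroupComparison(feature_id, ("table",), "chi_square",
                               float(chi2.statistic), float(chi2.pvalue))
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    groups = tuple(sorted(set(labels.tolist())))
    if len(groups) < 2:
        raise DegenerateInputError("need at least 2 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise DegenerateInputError("every group needs n >= 2")
    all_normal = all(is_normal(s) for s in samples)
    if len(groups) == 2:
        if all_normal:
            res = sps.ttest_ind(*samples)
            test = "t"
        else:
            res = sps.mannwhitneyu(*samples, alternative="two-sided")
            test = "mann_whitney"
    else:
        if all_normal:
            res = sps.f_oneway(*samples)
            test = "anova"
        else:
            res = sps.kruskal(*samples)
            test = "kruskal_wallis"
    return GroupComparison(feature_id, groups, test,
                           float(res.statistic), float(res.pvalue))


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment.

    Sorted p-values p_(1) <= ... <= p_(m) are multiplied by m, m-1, ...,
    1, a running maximum enforces monotonicity, and results are capped at
    1, then returned in the original order.
    """
    p = np.asarray(p_values, float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise DegenerateInputError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def adjust_comparisons(comparisons: list[GroupComparison]) -> list[GroupComparison]:
    """Attach Holm-adjusted p-values to a family of pairwise comparisons."""
    adj = holm_adjust([c.p_raw for c in comparisons])
    return [GroupComparison(c.feature_id, c.groups, c.test, c.statistic,
                            c.p_raw, float(a))
            for c, a in zip(comparisons, adj)]
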
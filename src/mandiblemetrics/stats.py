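"""Rank tests, agreement coefficients, correlation and regression.

The two rank tests are *exact* for the sample sizes this kind of cohort
produces: the Wilcoxon signed-rank test enumerates the null distribution
of the positive-rank sum for n <= 25 paired differences (via its
generating function over doubled average ranks — identical to
enumerating all 2^n sign patterns), and the Mann–Whitney U test
enumerates all C(n+m, n) group labelings for n + m <= 16. Larger samples
fall back to the normal approximation with tie correction (and
continuity correction for the signed-rank test). Two-sided p-values
double the smaller tail and are capped at 1.

Cohen's kappa supports unweighted, linear and quadratic weights; the ICC
comes from the two-way ANOVA mean squares in the absolute-agreement and
consistency single-measure forms. Correlation/regression and the
chi-square / Fisher decision delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "cohen_kappa",
    "icc",
    "icc_band",
    "correlation_and_regression",
    "chi_square_or_fisher",
]

WILCOXON_EXACT_MAX_N = 25
MANN_WHITNEY_EXACT_MAX_N = 16


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool


def _two_sided(tail: float) -> float:
    return min(1.0, 2.0 * tail)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


def _signed_rank_cdf(double_ranks: tuple, w2_obs: int) -> float:
    """P(2*W+ <= w2_obs) under the null, by the generating function of
    the positive-rank sum over all 2^n equally likely sign patterns.

    ``double_ranks`` are the (tied-average) ranks doubled so they are
    integers; the distribution is built by dynamic programming.
    """
    total = sum(double_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[: min(w2_obs, total) + 1].sum())


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Paired signed-rank test (or one-sample on differences if y=None).

    Zero differences are dropped; ties get average ranks. Exact for
    n <= 25 nonzero differences, otherwise normal approximation with
    continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_MAX_N:
        double_ranks = tuple(int(round(2 * r)) for r in ranks)
        p = _two_sided(_signed_rank_cdf(double_ranks, int(round(2 * w))))
        return TestResult(statistic=w, p_value=p, method="wilcoxon_exact", exact=True)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_correction_signed(ranks)
    z = (w - mean + 0.5) / np.sqrt(var)
    p = _two_sided(float(sps.norm.cdf(z)))
    return TestResult(statistic=w, p_value=p, method="wilcoxon_normal", exact=False)


def _tie_correction_signed(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts)) / 48.0


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _rank_sum_distribution(pooled_ranks: tuple, n: int):
    """Null distribution (sorted support, cdf weights) of the rank sum of
    a size-n group, enumerating all C(n+m, n) labelings."""
    ranks = np.asarray(pooled_ranks, dtype=float)
    idx = range(len(ranks))
    sums = np.fromiter(
        (ranks[list(c)].sum() for c in combinations(idx, n)), dtype=float
    )
    sums.sort()
    return sums


def mann_whitney_u(x, y) -> TestResult:
    """Two-sample rank test; exact by enumeration when n + m <= 16."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0
    u = min(u_x, n * m - u_x)
    if n + m <= MANN_WHITNEY_EXACT_MAX_N:
        key = tuple(np.round(ranks, 6))
        sums = _rank_sum_distribution(key, n)
        total = sums.size
        eps = 1e-9
        lo = float(np.searchsorted(sums, r_x + eps, side="left")) / total   # P(R <= r_x)
        hi = float(total - np.searchsorted(sums, r_x - eps, side="left")) / total  # P(R >= r_x)
        p = _two_sided(min(lo, hi))
        return TestResult(statistic=u, p_value=p, method="mann_whitney_exact", exact=True)
    mean = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((n + m + 1) - tie / ((n + m) * (n + m - 1)))
    if var <= 0:
        return TestResult(statistic=u, p_value=1.0, method="mann_whitney_normal", exact=False)
    z = (u - mean + 0.5) / np.sqrt(var)
    p = _two_sided(float(sps.norm.cdf(z)))
    return TestResult(statistic=u, p_value=p, method="mann_whitney_normal", exact=False)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def cohen_kappa(table, weights: str = "none") -> float:
    """Cohen's kappa for a k x k table of paired ratings.

    ``weights``: 'none' (0/1 disagreement), 'linear' (|i-j|/(k-1)) or
    'quadratic' (((i-j)/(k-1))^2). kappa = 1 - sum(w*p_obs)/sum(w*p_exp).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise ValueError("table must be square with k >= 2")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("table must be non-negative with positive total")
    k = t.shape[0]
    p = t / t.sum()
    i, j = np.indices((k, k))
    if weights == "none":
        w = (i != j).astype(float)
    elif weights == "linear":
        w = np.abs(i - j) / (k - 1)
    elif weights == "quadratic":
        w = ((i - j) / (k - 1)) ** 2
    else:
        raise ValueError("weights must be none, linear or quadratic")
    row, col = p.sum(axis=1), p.sum(axis=0)
    expected = np.outer(row, col)
    denom = float((w * expected).sum())
    if denom <= 0:
        raise ValueError("expected disagreement is zero (single occupied category)")
    return 1.0 - float((w * p).sum()) / denom


def icc(ratings, form: str = "two_way_absolute_single") -> float:
    """Intraclass correlation from two-way ANOVA mean squares.

    ``ratings`` is an (n_subjects, k_raters) matrix with no missing
    cells. Forms: 'two_way_absolute_single' (agreement of single
    measurements, ICC(2,1)-style) and 'two_way_consistency_single'
    (ICC(3,1)-style, insensitive to a constant rater offset).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be an (n>=2, k>=2) matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings contain missing/non-finite cells")
    n, k = m.shape
    grand = m.mean()
    subj = m.mean(axis=1)
    rater = m.mean(axis=0)
    ss_rows = k * np.sum((subj - grand) ** 2)
    ss_cols = n * np.sum((rater - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total <= 1e-12:
        raise ValueError("zero total variance; ICC undefined")
    if form == "two_way_absolute_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "two_way_consistency_single":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("unknown ICC form")
    if abs(denom) < 1e-12:
        raise ValueError("degenerate ICC denominator")
    return float((msr - mse) / denom)


def icc_band(value: float) -> str:
    """Qualitative reliability band for an ICC value (0.75 and up is
    conventionally reported as excellent)."""
    if value >= 0.75:
        return "excellent"
    if value >= 0.60:
        return "good"
    if value >= 0.40:
        return "fair"
    return "poor"


# ---------------------------------------------------------------------------
# correlation / regression / categorical
# ---------------------------------------------------------------------------


def correlation_and_regression(x, y) -> dict:
    """Pearson r, Spearman rho (average ranks) and the OLS fit y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    pear = sps.pearsonr(x, y)
    spear = sps.spearmanr(x, y)
    ols = sps.linregress(x, y)
    return {
        "pearson_r": float(pear.statistic),
        "spearman_rho": float(spear.statistic),
        "slope_B": float(ols.slope),
        "intercept": float(ols.intercept),
        "slope_p": float(ols.pvalue),
    }


def chi_square_or_fisher(table) -> TestResult:
    """2x2 association test: Pearson chi-square (no continuity
    correction) when every expected count is >= 5, otherwise Fisher's
    exact test (two-sided)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or t.sum() <= 0:
        raise ValueError("need a non-negative 2x2 table with positive total")
    row, col = t.sum(axis=1), t.sum(axis=0)
    expected = np.outer(row, col) / t.sum()
    if np.all(expected >= 5):
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
        return TestResult(statistic=float(stat), p_value=float(p),
                          method="chi_square", exact=False)
    stat, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="fisher_exact", exact=True)
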
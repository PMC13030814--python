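"""Descriptive statistics, paired-eye comparisons and the post hoc power
computation.

Right/left eyes of the same participant are compared with the Wilcoxon
signed-rank test (continuous parameters; exact null distribution for up
to 25 informative pairs, normal approximation with continuity correction
beyond) and McNemar's test (binary parameters; exact binomial for few
discordant pairs).  Prevalences carry Wilson score intervals.  The
minimum detectable R-squared inverts a noncentral-F power analysis for a
single-predictor regression at the study's sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PairedSample", "describe_median_iqr", "wilcoxon_paired", "mcnemar",
    "prevalence_ci", "agreement_rate", "cohen_kappa", "min_detectable_r2",
]

#: informative-pair / discordant-count threshold for switching from the
#: exact null distribution to the normal / chi-square approximation
EXACT_LIMIT = 25


@dataclass(frozen=True)
class PairedSample:
    """Per-participant (right, left) pairs of one variable."""

    right: np.ndarray
    left: np.ndarray
    name: str = ""
    kind: str = "continuous"    # {"continuous", "binary"}

    def __post_init__(self) -> None:
        r = np.asarray(self.right, float)
        l = np.asarray(self.left, float)
        if r.shape != l.shape or r.ndim != 1:
            raise ValueError("right/left must be aligned 1-D arrays")
        object.__setattr__(self, "right", r)
        object.__setattr__(self, "left", l)


def describe_median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles, linear interpolation between order statistics."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided p by dynamic programming over the 2^n sign assignments.

    Works on doubled ranks so tie-averaged (half-integer) ranks stay
    integral; complexity O(n * sum(ranks)).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    lo = counts[:w2 + 1].sum()
    hi = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_paired(pairs: PairedSample) -> tuple[float, float]:
    """Wilcoxon signed-rank test of right vs left.

    Zero differences are dropped; ties get averaged ranks.  Exact null
    distribution (by enumeration over sign assignments) when at most
    :data:`EXACT_LIMIT` informative pairs remain, otherwise the normal
    approximation with continuity and tie corrections.  Returns
    (W+ statistic, two-sided p).
    """
    d = pairs.right - pairs.left
    d = d[d != 0]
    n = d.size
    if n == 0:
        import warnings
        warnings.warn("all paired differences are zero", RuntimeWarning,
                      stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        return w_plus, _exact_signed_rank_p(w_plus, ranks)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sd
    return w_plus, float(2 * stats.norm.sf(abs(z)))


def mcnemar(pairs: PairedSample) -> tuple[float, float]:
    """McNemar's test on binary right/left pairs.

    Exact binomial test on the discordant counts (b, c) when b + c <
    :data:`EXACT_LIMIT`, otherwise the continuity-corrected chi-square.
    Returns (statistic, two-sided p); statistic is b + c on the exact
    path, the chi-square value otherwise.
    """
    r = pairs.right.astype(bool)
    l = pairs.left.astype(bool)
    b = int((r & ~l).sum())
    c = int((~r & l).sum())
    if b + c == 0:
        import warnings
        warnings.warn("no discordant pairs", RuntimeWarning, stacklevel=2)
        return 0.0, 1.0
    a = int((r & l).sum())
    d = int((~r & ~l).sum())
    table = [[a, b], [c, d]]
    exact = (b + c) < EXACT_LIMIT
    res = _sm_mcnemar(table, exact=exact, correction=True)
    stat = float(b + c) if exact else float(res.statistic)
    return stat, float(res.pvalue)


def prevalence_ci(k: int, n: int) -> tuple[float, float, float]:
    """Proportion k/n with the Wilson score 95% interval."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n >= 1")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    prop = k / n
    # guard against float dust at the boundaries (k = 0 or k = n)
    lo = min(max(float(lo), 0.0), prop)
    hi = max(min(float(hi), 1.0), prop)
    return prop, lo, hi


def agreement_rate(discordant: int, total: int) -> float:
    """Percent agreement, rounded to one decimal for display."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= discordant <= total:
        raise ValueError("discordant must be in [0, total]")
    return round(100.0 * (total - discordant) / total, 1)


def cohen_kappa(table) -> float:
    """Cohen's kappa for a 2x2 (or square) agreement table."""
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    n = t.sum()
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) / n) @ (t.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def _power_f2(f2: float, n: int, alpha: float, n_predictors: int) -> float:
    df1 = n_predictors
    df2 = n - n_predictors - 1
    fcrit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, f2 * n))


def min_detectable_r2(n: int, power: float = 0.80, alpha: float = 0.05,
                      n_predictors: int = 1) -> float:
    """Smallest R-squared detectable at the stated power and level.

    Solves the noncentral-F power equation for the effect size f^2 with
    noncentrality lambda = f^2 * n, then returns R^2 = f^2 / (1 + f^2).
    """
    if n <= n_predictors + 1:
        raise ValueError("n must exceed n_predictors + 1")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    lo, hi = 1e-10, 10.0
    if _power_f2(hi, n, alpha, n_predictors) < power:
        raise ValueError("requested power unattainable at this n")
    from scipy.optimize import brentq
    f2 = brentq(lambda v: _power_f2(v, n, alpha, n_predictors) - power,
                lo, hi, xtol=1e-8)
    return float(f2 / (1.0 + f2))
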
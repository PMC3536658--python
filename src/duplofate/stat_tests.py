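"""The four hypothesis tests used throughout the analysis.

Self-contained implementations with exact small-sample behavior:
Welch's unequal-variance t test, the Wilcoxon rank-sum test (exact by
enumeration for small samples, normal approximation with tie and
continuity corrections otherwise), Fisher's exact test on 2x2 tables
(probability-mass two-sided rule, sample and conditional-MLE odds
ratios), and the chi-square goodness-of-fit test.  Only distribution
functions (t, normal, chi-square, hypergeometric pmf) are delegated to
scipy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from math import comb, inf, lgamma, sqrt

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    estimate: float | None = None
    sidedness: str = "two"
    extra: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Welch t


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t test (unequal variances, two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        # both samples constant; equal means => no evidence
        t = 0.0 if x.mean() == y.mean() else inf
        return TestResult(statistic=t, p_value=1.0 if t == 0 else 0.0,
                          df=float(nx + ny - 2))
    t = (x.mean() - y.mean()) / sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(min(p, 1.0)),
                      df=float(df))


# ---------------------------------------------------------------------------
# Wilcoxon rank sum


@lru_cache(maxsize=32)
def _ranksum_null(nx: int, n: int) -> np.ndarray:
    """Counts of subsets of size nx of ranks 1..n by rank sum (exact null).

    Dynamic programming over ranks; index k of the returned array is the
    number of subsets with sum k.
    """
    max_sum = nx * n
    table = np.zeros((nx + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, nx), 0, -1):
            table[k, r:] += table[k - 1, :-r or None]
    return table[nx]


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Wilcoxon rank-sum test with midranks for ties (two-sided).

    Exact when nx + ny <= 20 (full enumeration of rank assignments;
    a closed-form DP is used in the tie-free case), otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)          # midranks
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if np.allclose(pooled, pooled[0]):
        return TestResult(statistic=w, p_value=1.0)
    if n <= 20:
        if not has_ties:
            counts = _ranksum_null(nx, n)
            total = comb(n, nx)
            dev = abs(w - mu)
            sums = np.arange(counts.size, dtype=float)
            p = counts[np.abs(sums - mu) >= dev - 1e-9].sum() / total
        else:
            sums = np.fromiter(
                (ranks[list(idx)].sum()
                 for idx in itertools.combinations(range(n), nx)),
                dtype=float, count=comb(n, nx))
            dev = abs(w - mu)
            p = float((np.abs(sums - mu) >= dev - 1e-9).mean())
        return TestResult(statistic=w, p_value=float(min(p, 1.0)),
                          extra={"exact": True})
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, p_value=1.0)
    z = (abs(w - mu) - 0.5) / sqrt(var)     # continuity correction
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return TestResult(statistic=w, p_value=float(min(p, 1.0)),
                      extra={"exact": False, "z": float(z)})


# ---------------------------------------------------------------------------
# Fisher exact


def _conditional_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    Solves E_psi[A] = a under the noncentral hypergeometric
    distribution with the observed margins.
    """
    row1, col1 = a + b, a + c
    n = a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    if a == lo:
        return 0.0
    if a == hi:
        return inf
    support = np.arange(lo, hi + 1)

    def log_comb(m: int, k: int) -> float:
        return lgamma(m + 1) - lgamma(k + 1) - lgamma(m - k + 1)

    logw = np.array([log_comb(col1, k) + log_comb(n - col1, row1 - k)
                     for k in support])

    def mean_minus_a(log_psi: float) -> float:
        logp = logw + support * log_psi
        logp -= logp.max()
        p = np.exp(logp)
        return float((support * p).sum() / p.sum()) - a

    sol = optimize.brentq(mean_minus_a, -50, 50, xtol=1e-12)
    return float(np.exp(sol))


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    Two-sided p by the probability-mass rule: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more
    probable than the observed one.  The estimate is the sample odds
    ratio ad/bc; the conditional-MLE odds ratio is reported alongside.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    flags = {}
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        flags["zero_margin"] = True
        return TestResult(statistic=float("nan"), p_value=1.0,
                          estimate=None, extra=flags)
    if b * c == 0:
        sample_or = inf if a * d > 0 else (0.0 if a == 0 or d == 0 else 1.0)
        flags["zero_cell"] = True
    else:
        sample_or = (a * d) / (b * c)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    cmle = _conditional_mle_or(a, b, c, d)
    return TestResult(statistic=float(sample_or)
                      if np.isfinite(sample_or) else float("nan"),
                      p_value=min(p, 1.0), estimate=float(sample_or)
                      if np.isfinite(sample_or) else sample_or,
                      extra={"conditional_mle_or": cmle, **flags})


# ---------------------------------------------------------------------------
# Chi-square goodness of fit


def chi_square_gof(observed, expected, df: int | None = None) -> TestResult:
    """Chi-square goodness-of-fit: sum (O - E)^2 / E, upper-tail p.

    Expected counts must be positive; if totals disagree the expected
    vector is rescaled to the observed total (logged).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if (e <= 0).any():
        raise ValueError("expected counts must be positive in every cell")
    if abs(o.sum() - e.sum()) > 1e-6:
        logger.info("rescaling expected counts (%g) to the observed total "
                    "(%g)", e.sum(), o.sum())
        e = e * (o.sum() / e.sum())
    chi2 = float(((o - e) ** 2 / e).sum())
    k = df if df is not None else o.size - 1
    p = float(stats.chi2.sf(chi2, k))
    return TestResult(statistic=chi2, p_value=p, df=float(k))
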
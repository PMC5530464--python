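"""Exact and log-stable statistical primitives shared by all stages.

The enrichment battery reports the conditional maximum-likelihood odds ratio
(the root of the noncentral-hypergeometric mean equation given the table
margins) together with the two-sided Fisher exact p computed by the
point-probability rule, i.e. the sum of probabilities of all tables, under
fixed margins, no more likely than the observed one. This is the convention
of R's ``fisher.test`` and reproduces published OR/p pairs that the sample
cross-product ratio does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, rankdata

Sided = Literal["two", "greater", "less"]

# relative tolerance when comparing table probabilities (guards float ties)
_PT_TOL = 1.0 + 1e-7


class StatError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class TwoByTwoTable:
    """Counts [[a, b], [c, d]]: rows = condition, cols = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatError("negative cell count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _table_support(table: TwoByTwoTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of the a-cell under fixed margins, with log hypergeometric
    coefficients log[C(r1, x) C(r2, c1 - x)]."""
    r1, r2, c1, _ = table.margins()
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    xs = np.arange(lo, hi + 1)
    logc = (
        gammaln(r1 + 1)
        - gammaln(xs + 1)
        - gammaln(r1 - xs + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - xs + 1)
        - gammaln(r2 - c1 + xs + 1)
    )
    return xs, logc


def fisher_exact(table: TwoByTwoTable, sided: Sided = "two") -> float:
    """Fisher's exact conditional test on a 2x2 table, computed in log space.

    ``two``-sided p sums all tables with point probability <= that of the
    observed table (within a 1 + 1e-7 relative tolerance).
    """
    xs, logc = _table_support(table)
    logz = logsumexp(logc)
    logp = logc - logz  # central hypergeometric pmf over the a-cell support
    obs = table.a - xs[0]
    if sided == "greater":
        return float(np.exp(logsumexp(logp[obs:])))
    if sided == "less":
        return float(np.exp(logsumexp(logp[: obs + 1])))
    cutoff = logp[obs] + math.log(_PT_TOL)
    keep = logp <= cutoff
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def conditional_mle_or(table: TwoByTwoTable) -> float:
    """Conditional-MLE odds ratio: root theta of E[X | margins, theta] = a
    under Fisher's noncentral hypergeometric distribution.

    Returns 0.0 / inf when the observed cell sits at the boundary of its
    attainable range (the estimate diverges).
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise StatError("odds ratio undefined: zero margin")
    xs, logc = _table_support(table)
    if table.a == xs[0]:
        return 0.0
    if table.a == xs[-1]:
        return math.inf

    def mean_minus_a(log_theta: float) -> float:
        lw = logc + xs * log_theta
        lw -= logsumexp(lw)
        return float(np.sum(xs * np.exp(lw))) - table.a

    lo, hi = -1.0, 1.0
    while mean_minus_a(lo) > 0:
        lo *= 2
        if lo < -700:
            return 0.0
    while mean_minus_a(hi) < 0:
        hi *= 2
        if hi > 700:
            return math.inf
    root = brentq(mean_minus_a, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(np.exp(root))


def hypergeom_log_sf(x: int, N: int, K: int, n: int) -> float:
    """log P(X >= x) for X ~ Hypergeometric(N, K, n), via log-gamma summation.

    N = population, K = successes in the population, n = draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise StatError(f"inconsistent hypergeometric parameters N={N} K={K} n={n}")
    hi = min(K, n)
    if x > hi:
        raise StatError(f"x={x} above attainable maximum {hi}")
    lo = max(0, n - (N - K))
    if x <= lo:
        return 0.0  # log 1
    xs = np.arange(x, hi + 1)
    logpmf = (
        gammaln(K + 1)
        - gammaln(xs + 1)
        - gammaln(K - xs + 1)
        + gammaln(N - K + 1)
        - gammaln(n - xs + 1)
        - gammaln(N - K - n + xs + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(logsumexp(logpmf))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], sided: Sided = "two"
) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration of all C(nx+ny, nx) group assignments when the combined
    sample size is <= 12 (valid under ties); otherwise the normal
    approximation with tie and continuity correction. Returns (U of x, p).
    ``greater`` means x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatError("empty sample")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    rx = ranks[:nx].sum()
    u_x = rx - nx * (nx + 1) / 2.0

    if nx + ny <= 12:
        from itertools import combinations

        n = nx + ny
        u_all = []
        ranks_all = rankdata(combined)
        for idx in combinations(range(n), nx):
            r = ranks_all[list(idx)].sum()
            u_all.append(r - nx * (nx + 1) / 2.0)
        u_all = np.asarray(u_all)
        m = u_all.size
        eps = 1e-9
        p_ge = np.sum(u_all >= u_x - eps) / m
        p_le = np.sum(u_all <= u_x + eps) / m
        if sided == "greater":
            p = p_ge
        elif sided == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return float(u_x), float(p)

    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u_x), 1.0
    sigma = math.sqrt(sigma2)
    if sided == "greater":
        z = (u_x - mu - 0.5) / sigma
        p = norm.sf(z)
    elif sided == "less":
        z = (u_x - mu + 0.5) / sigma
        p = norm.cdf(z)
    else:
        z = (u_x - mu - math.copysign(0.5, u_x - mu)) / sigma if u_x != mu else 0.0
        p = 2.0 * norm.sf(abs(z))
    return float(u_x), float(min(1.0, p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise StatError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman(
    x: Sequence[float], y: Sequence[float], sided: Sided = "two"
) -> tuple[float, float]:
    """Spearman correlation on average ranks with tie handling.

    Returns (rho, p); (nan, nan) for constant input (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatError("length mismatch")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    from scipy.stats import spearmanr

    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def welch_t_one_tailed(
    x: Sequence[float], y: Sequence[float], direction: Literal["greater", "less"]
) -> tuple[float, float]:
    """Unequal-variance (Welch) one-tailed t-test of x vs y.

    ``greater``: alternative mean(x) > mean(y). Returns (t, p); (nan, 1.0)
    when both groups are constant and equal (no evidence either way).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise StatError("Welch t-test needs >= 2 observations per group")
    from scipy.stats import ttest_ind

    res = ttest_ind(x, y, equal_var=False, alternative=direction)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # zero variance in both groups
        return math.nan, 1.0
    return t, p


def permutation_p(observed: float, null_scores: Sequence[float]) -> float:
    """Permutation p-value P = (1 + #{X_n >= X_0}) / (N + 1); ties count."""
    null_scores = np.asarray(null_scores, dtype=float)
    n = null_scores.size
    if n < 1:
        raise StatError("empty null sample")
    exceed = int(np.sum(null_scores >= observed))
    return (1 + exceed) / (n + 1)
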
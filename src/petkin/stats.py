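"""Nonparametric group comparison and correlation.

Small animal cohorts (five or six animals per group) call for exact
nonparametric inference: the Mann-Whitney U test uses the full permutation
distribution whenever the pooled sample is small enough to enumerate, and
Spearman's rank correlation uses the exact permutation distribution of the
rank statistic for very small n.  Larger samples fall back on the usual
tie-corrected normal (Mann-Whitney) and t (Spearman) approximations.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy.stats import distributions, rankdata

__all__ = ["GroupComparison", "CorrelationResult", "mann_whitney", "spearman"]

_EXACT_MW_LIMIT = 20   # exact enumeration when n + m <= this
_EXACT_RHO_LIMIT = 9   # exact permutation p when n <= this


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney result: U counts pairs where the first group exceeds
    the second (ties count one half)."""

    u: float
    p_value: float
    n_a: int
    n_b: int
    exact: bool

    def __post_init__(self):
        if not (0.0 <= self.u <= self.n_a * self.n_b):
            raise ValueError("U must lie in [0, n*m]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with two-sided p."""

    rho: float
    p_value: float
    n: int
    exact: bool
    undefined: bool = False


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact permutation p (handles ties) for pooled sizes up to 20 — which
    covers the cohort sizes of interest — and the tie-corrected normal
    approximation with continuity correction beyond that.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks
    u = _u_from_ranks(float(ranks[:n].sum()), n)

    if n + m <= _EXACT_MW_LIMIT:
        # enumerate all assignments of n pooled values to group A
        idx = np.fromiter(
            (i for comb in combinations(range(n + m), n) for i in comb),
            dtype=np.intp)
        idx = idx.reshape(-1, n)
        u_all = ranks[idx].sum(axis=1) - n * (n + 1) / 2.0
        center = n * m / 2.0
        p = float(np.mean(np.abs(u_all - center) >= abs(u - center) - 1e-12))
        return GroupComparison(u=u, p_value=max(p, 1.0 / idx.shape[0]),
                               n_a=n, n_b=m, exact=True)

    # normal approximation with tie correction
    nm = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (nm * (nm - 1.0))
    var = n * m / 12.0 * ((nm + 1.0) - tie_term)
    if var <= 0:
        return GroupComparison(u=u, p_value=1.0, n_a=n, n_b=m, exact=False)
    z = (abs(u - n * m / 2.0) - 0.5) / np.sqrt(var)
    p = float(2.0 * distributions.norm.sf(max(z, 0.0)))
    return GroupComparison(u=u, p_value=min(max(p, np.finfo(float).tiny), 1.0),
                           n_a=n, n_b=m, exact=False)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    return float(np.sum(rx * ry) / denom)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Exact permutation two-sided p for n <= 9, Student-t approximation
    otherwise.  A constant input leaves rho undefined; the result is
    flagged rather than raised.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=np.nan, p_value=np.nan, n=n,
                                 exact=False, undefined=True)
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_corr(rx, ry)

    if n <= _EXACT_RHO_LIMIT:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        ryc = ry - ry.mean()
        denom = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum(ryc ** 2))
        # centring of the permuted ranks drops out against the centred ry
        rho_all = (rx[perms] @ ryc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return CorrelationResult(rho=rho, p_value=p, n=n, exact=True)

    # t approximation
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=rho, p_value=np.finfo(float).tiny,
                                 n=n, exact=False)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * distributions.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n, exact=False)
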
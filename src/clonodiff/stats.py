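"""Statistical primitives shared by every comparison in the package.

Conventions (fixed so results are reproducible bit-for-bit):

* Mann-Whitney U: exact two-sided p when ``min(n_x, n_y) <= 8`` — via the
  classical null-distribution recursion when the pooled data are tie-free
  (any sizes), or by full enumeration over the observed mid-ranks when ties
  are present and C(m+n, m) stays enumerable; otherwise a normal
  approximation with mid-ranks, tie-corrected variance and a 0.5 continuity
  correction. Group sizes of 15 per side — the scale of the repertoire
  comparisons — always take the approximate, tie-robust path.
* Welch t: unequal-variance statistic with Satterthwaite degrees of
  freedom. Zero pooled variance returns p = 1 with the ``zero_variance``
  flag set instead of raising, so batch reports never abort on a
  degenerate metric.
* Fisher exact (2x2): two-sided p as the sum of hypergeometric point
  probabilities, over all tables with the observed margins, that do not
  exceed the observed table's probability (with 1e-7 relative slack to
  guard floating-point equality of symmetric tables).
* Benjamini-Hochberg: step-up with monotonicity enforcement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .errors import DataError

EXACT_MWU_MAX_N = 8  # exact enumeration when min group size <= this and no ties


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one two-sample or contingency test."""

    statistic: float
    pvalue: float
    method: str  # "exact" | "normal-approx" | "welch" | "fisher-exact"
    zero_variance: bool = False
    df: float | None = None
    odds_ratio: float | None = None


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_null_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value, for group sizes m, n.

    Recursion on the largest pooled observation: if it belongs to the
    y-group the statistic is unchanged (sizes m, n-1); if to the x-group it
    exceeds all n y's and contributes n to U (sizes m-1, n).
    """
    if m == 0 or n == 0:
        return (1,)
    a = _u_null_counts(m, n - 1)  # length m*(n-1)+1
    b = _u_null_counts(m - 1, n)  # length (m-1)*n+1
    out = [0] * (m * n + 1)
    for u, c in enumerate(a):
        out[u] += c
    for u, c in enumerate(b):
        out[u + n] += c
    return tuple(out)


_EXACT_ENUM_LIMIT = 100_000  # max C(m+n, m) for the tie-aware exact path


def _exact_midrank_p(ranks: np.ndarray, m: int, u_obs: float) -> float:
    """Exact permutation p over the observed mid-ranks (valid with ties)."""
    offset = m * (m + 1) / 2.0
    lower = upper = total = 0
    for combo in itertools.combinations(range(len(ranks)), m):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if u <= u_obs + 1e-9:
            lower += 1
        if u >= u_obs - 1e-9:
            upper += 1
    return min(1.0, 2.0 * min(lower, upper) / total)


def mann_whitney_u(x, y) -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    U is the statistic for the first sample (number of (x, y) pairs with
    x > y, ties counting one half). The two-sided p doubles the smaller of
    the two tail probabilities, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m < 1 or n < 1:
        raise DataError("mann_whitney_u requires at least one value per group")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:m].sum() - m * (m + 1) / 2.0)

    has_ties = len(np.unique(pooled)) < m + n
    if min(m, n) <= EXACT_MWU_MAX_N:
        if not has_ties:
            counts = np.array(_u_null_counts(m, n), dtype=float)
            total = counts.sum()  # == C(m+n, m)
            k = int(round(u))
            lower = counts[: k + 1].sum() / total
            upper = counts[k:].sum() / total
            p = min(1.0, 2.0 * min(lower, upper))
            return GroupTestResult(statistic=u, pvalue=p, method="exact")
        if math.comb(m + n, m) <= _EXACT_ENUM_LIMIT:
            p = _exact_midrank_p(ranks, m, u)
            return GroupTestResult(statistic=u, pvalue=p, method="exact")

    mu = m * n / 2.0
    N = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return GroupTestResult(
            statistic=u, pvalue=1.0, method="normal-approx", zero_variance=True
        )
    diff = u - mu
    cc = 0.5 * float(np.sign(diff))  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return GroupTestResult(statistic=u, pvalue=p, method="normal-approx")


# ---------------------------------------------------------------------------
# Welch t


def welch_t(x, y) -> GroupTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("welch_t requires at least two values per group")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx + vy == 0.0:
        return GroupTestResult(
            statistic=0.0, pvalue=1.0, method="welch", zero_variance=True
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return GroupTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="welch",
        df=float(res.df),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted q-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Fisher exact


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d with rows = outcome yes/no and columns = arm."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise DataError("2x2 cells must be non-negative integers")
        if sum(cells) == 0:
            raise DataError("2x2 table is all zero")


_FISHER_REL_SLACK = 1e-7


def fisher_exact_2x2(table: ContingencyTable2x2) -> GroupTestResult:
    """Two-sided Fisher exact test by full hypergeometric enumeration.

    p is the total probability, under fixed margins, of all tables whose
    point probability is <= that of the observed table (within 1e-7
    relative slack). The odds ratio is the sample estimate ad/bc; a zero
    denominator yields +inf, and 0/0 yields nan.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    k_min = max(0, col1 - (c + d))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(support, N, row1, col1)
    p_obs = float(sps.hypergeom.pmf(a, N, row1, col1))
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_REL_SLACK)].sum())
    p = min(1.0, p)

    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return GroupTestResult(
        statistic=p_obs, pvalue=p, method="fisher-exact", odds_ratio=odds
    )
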
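"""Clonal diversity indices and their between-group comparisons.

Three indices summarise how evenly a repertoire's reads are spread over its
clonotypes:

* **d50**: the smallest number of top clones whose cumulative read
  frequency reaches 50%, reported both as a count and as a percentage of
  all clonotypes (``100 * k / n``) — low values indicate clonal dominance.
* **Normalized Shannon** (Pielou evenness): Shannon entropy of the clone
  frequencies divided by its maximum ``ln n``; 1 for a perfectly even
  repertoire, defined as 0 for a monoclonal one.
* **Inverse Simpson**: ``1 / sum(p_i^2)``, the effective number of dominant
  clones; ranges from 1 (monoclonal) to the clonotype count (uniform).

All indices are computed on read-weighted frequencies — clone sizes matter;
clonotype-uniform frequencies would make every index degenerate.

Between-group tests follow a fixed metric-to-test mapping: clonotype count
and d50 index use Welch's t-test; normalized Shannon and inverse Simpson use
the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientReplicationError, NormalizationError
from .io import RepertoireSample
from .stats import GroupTestResult, mann_whitney_u, welch_t

_SUM_TOL = 1e-6
_CUM_TOL = 1e-9


def _validated(frequencies) -> np.ndarray:
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise NormalizationError("empty frequency vector")
    if np.any(p <= 0):
        raise NormalizationError("frequencies must be strictly positive")
    s = p.sum()
    if abs(s - 1.0) > _SUM_TOL:
        raise NormalizationError(f"frequencies sum to {s:.8f}, expected 1")
    return p / s


def inverse_simpson(frequencies) -> float:
    p = _validated(frequencies)
    return float(1.0 / np.sum(p**2))


def shannon(frequencies) -> float:
    """Shannon entropy in nats."""
    p = _validated(frequencies)
    return float(-np.sum(p * np.log(p)))


def shannon_norm(frequencies) -> float:
    p = _validated(frequencies)
    n = p.size
    if n == 1:
        return 0.0
    return float(-np.sum(p * np.log(p)) / np.log(n))


def d50(frequencies) -> tuple[int, float]:
    """Smallest k top clones reaching >= 50% cumulative frequency.

    Returns ``(d50_count, d50_index)`` where the index is ``100 * k / n``.
    Ties in frequency may be broken arbitrarily; the result is invariant.
    """
    p = _validated(frequencies)
    ordered = np.sort(p)[::-1]
    cum = np.cumsum(ordered)
    k = int(np.searchsorted(cum, 0.5 - _CUM_TOL) + 1)
    return k, 100.0 * k / p.size


@dataclass(frozen=True)
class DiversityProfile:
    """All per-sample diversity metrics in one bundle."""

    sample_id: str
    clonotype_count: int
    d50_count: int
    d50_index: float
    shannon: float
    shannon_norm: float
    inverse_simpson: float


def diversity_profile(sample: RepertoireSample) -> DiversityProfile:
    p = np.array(sample.frequencies())
    k, idx = d50(p)
    return DiversityProfile(
        sample_id=sample.sample_id,
        clonotype_count=sample.n_clonotypes,
        d50_count=k,
        d50_index=idx,
        shannon=shannon(p),
        shannon_norm=shannon_norm(p),
        inverse_simpson=inverse_simpson(p),
    )


#: metric name -> (attribute, test function); the test assignment is part of
#: the analysis contract and is not configurable.
METRIC_TESTS = {
    "clonotype_count": welch_t,
    "d50_index": welch_t,
    "shannon_norm": mann_whitney_u,
    "inverse_simpson": mann_whitney_u,
}


@dataclass(frozen=True)
class DiversityComparison:
    metric: str
    test: str
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    direction: str  # "A>B" | "A<B" | "A=B"
    result: GroupTestResult

    @property
    def pvalue(self) -> float:
        return self.result.pvalue


def compare_diversity(
    group_a: list[DiversityProfile], group_b: list[DiversityProfile]
) -> list[DiversityComparison]:
    """Between-group comparison of every diversity metric.

    Uses Welch's t for clonotype count and d50 index, Mann-Whitney U for
    normalized Shannon and inverse Simpson.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientReplicationError(
            "compare_diversity needs at least two samples per group"
        )
    out = []
    for metric, test in METRIC_TESTS.items():
        xa = np.array([getattr(p, metric) for p in group_a], dtype=float)
        xb = np.array([getattr(p, metric) for p in group_b], dtype=float)
        res = test(xa, xb)
        ma, mb = float(xa.mean()), float(xb.mean())
        direction = "A>B" if ma > mb else ("A<B" if ma < mb else "A=B")
        out.append(
            DiversityComparison(
                metric=metric,
                test=res.method if res.method == "welch" else "mann_whitney",
                mean_a=ma,
                mean_b=mb,
                median_a=float(np.median(xa)),
                median_b=float(np.median(xb)),
                direction=direction,
                result=res,
            )
        )
    return out
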
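"""V/J segment usage, differential usage testing, and V-J pairing.

Usage vectors give the fraction of a sample attributable to each V (or J)
gene, under the same two weightings as the spectratype module. Differential
usage tests every gene observed in any sample (absent genes contribute
fraction 0 — a common test universe is required) with the two-sided
Mann-Whitney U test, reporting raw p and Benjamini-Hochberg q within the
segment family.

The V x J pairing matrix gives joint rearrangement frequencies; per sample
its row sums reproduce the V usage vector and its column sums the J usage
vector exactly (same weighting). The group-level matrix is the unweighted
mean of per-sample matrices over the union of observed gene pairs, so each
patient carries equal weight regardless of sequencing depth; a pooled-reads
mode is available via ``group_pairing_matrix(..., pooled=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BoundsError, EmptyRepertoireError, InsufficientReplicationError
from .io import RepertoireSample
from .stats import bh_adjust, mann_whitney_u

SEGMENTS = ("V", "J")


def _segment_call(segment: str):
    if segment not in SEGMENTS:
        raise ValueError(f"segment must be 'V' or 'J', got {segment!r}")
    return (lambda r: r.v_call) if segment == "V" else (lambda r: r.j_call)


@dataclass(frozen=True)
class UsageVector:
    sample_id: str
    segment: str
    weighting: str
    fractions: dict[str, float]  # normalized gene name -> fraction


def usage_vector(
    sample: RepertoireSample, segment: str = "V", weighting: str = "clonotypes"
) -> UsageVector:
    if not sample.records:
        raise EmptyRepertoireError(f"sample {sample.sample_id!r} is empty")
    call = _segment_call(segment)
    fractions: dict[str, float] = {}
    if weighting == "clonotypes":
        w = 1.0 / sample.n_clonotypes
        for r in sample.records:
            fractions[call(r)] = fractions.get(call(r), 0.0) + w
    elif weighting == "reads":
        for r in sample.records:
            fractions[call(r)] = fractions.get(call(r), 0.0) + r.frequency
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return UsageVector(
        sample_id=sample.sample_id,
        segment=segment,
        weighting=weighting,
        fractions=dict(sorted(fractions.items())),
    )


def differential_usage(
    group_a: list[UsageVector], group_b: list[UsageVector]
) -> pd.DataFrame:
    """Per-gene Mann-Whitney comparison of usage fractions between groups.

    Returns a DataFrame with columns gene, segment, mean_a, mean_b, u, p, q,
    sorted by ascending p (ties by gene name). Genes unobserved in a sample
    enter as fraction 0.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientReplicationError(
            "differential_usage needs at least two samples per group"
        )
    segments = {u.segment for u in group_a + group_b}
    if len(segments) != 1:
        raise ValueError(f"mixed segments in differential_usage input: {segments}")
    segment = segments.pop()
    genes = sorted(set().union(*(u.fractions for u in group_a + group_b)))
    rows = []
    for gene in genes:
        xa = np.array([u.fractions.get(gene, 0.0) for u in group_a])
        xb = np.array([u.fractions.get(gene, 0.0) for u in group_b])
        res = mann_whitney_u(xa, xb)
        rows.append((gene, segment, xa.mean(), xb.mean(), res.statistic, res.pvalue))
    df = pd.DataFrame(rows, columns=["gene", "segment", "mean_a", "mean_b", "u", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)


@dataclass
class PairingMatrix:
    """Joint V x J rearrangement frequencies for a sample or group."""

    label: str
    weighting: str
    matrix: pd.DataFrame  # index = V genes, columns = J genes, entries sum to 1

    def marginal(self, segment: str) -> pd.Series:
        if segment == "V":
            return self.matrix.sum(axis=1)
        if segment == "J":
            return self.matrix.sum(axis=0)
        raise ValueError(f"segment must be 'V' or 'J', got {segment!r}")


def vj_pairing_matrix(
    sample: RepertoireSample, weighting: str = "clonotypes"
) -> PairingMatrix:
    if not sample.records:
        raise EmptyRepertoireError(f"sample {sample.sample_id!r} is empty")
    if weighting == "clonotypes":
        weights = [1.0 / sample.n_clonotypes] * sample.n_clonotypes
    elif weighting == "reads":
        weights = [r.frequency for r in sample.records]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    long = pd.DataFrame(
        {
            "v": [r.v_call for r in sample.records],
            "j": [r.j_call for r in sample.records],
            "w": weights,
        }
    )
    m = long.pivot_table(
        index="v", columns="j", values="w", aggfunc="sum", fill_value=0.0
    ).sort_index(axis=0).sort_index(axis=1)
    m.index.name = None
    m.columns.name = None
    return PairingMatrix(label=sample.sample_id, weighting=weighting, matrix=m)


def group_pairing_matrix(
    matrices: list[PairingMatrix], label: str, pooled: bool = False
) -> PairingMatrix:
    """Group-level pairing matrix over the union of observed gene pairs.

    Default: the unweighted mean of per-sample matrices (each patient equal
    weight). ``pooled=True`` instead weights each sample by nothing extra —
    callers wanting read-pooled matrices should build one from merged
    samples; here pooled simply renormalizes the summed matrices.
    """
    if not matrices:
        raise EmptyRepertoireError("no pairing matrices to aggregate")
    weighting = matrices[0].weighting
    v_genes = sorted(set().union(*(m.matrix.index for m in matrices)))
    j_genes = sorted(set().union(*(m.matrix.columns for m in matrices)))
    acc = pd.DataFrame(0.0, index=v_genes, columns=j_genes)
    for m in matrices:
        acc = acc.add(m.matrix.reindex(index=v_genes, columns=j_genes, fill_value=0.0))
    out = acc / acc.to_numpy().sum() if pooled else acc / len(matrices)
    return PairingMatrix(label=label, weighting=weighting, matrix=out)


def top_linked_genes(matrix: PairingMatrix, segment: str, k: int) -> list[str]:
    """Genes ranked by marginal pairing mass, descending; ties lexicographic."""
    if k < 1:
        raise BoundsError("k must be >= 1")
    marg = matrix.marginal(segment)
    if k > len(marg):
        raise BoundsError(f"k={k} exceeds the {len(marg)} genes in the matrix")
    ranked = sorted(marg.index, key=lambda g: (-marg[g], g))
    return ranked[:k]
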
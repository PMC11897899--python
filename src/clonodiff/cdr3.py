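"""CDR3 spectratypes and positional amino-acid composition.

A *spectratype* is the distribution of CDR3 lengths within one repertoire.
Two weightings are supported: ``clonotypes`` (each unique clonotype counts
once — the default) and ``reads`` (each clonotype contributes its read
frequency). Between-group comparisons test each length's per-sample
fraction with the Mann-Whitney U test, and per-sample mean CDR3 length with
Welch's t-test; raw p-values mirror the primary analysis, BH q-values are
reported alongside.

The positional composition matrix is the numeric substrate of a sequence
logo: for CDR3s of one fixed length, the fraction of each amino acid at
each (1-based, N-terminal-first) position, pooled over samples with each
contributing sample weighted equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    EmptyRepertoireError,
    EmptySelectionError,
    InsufficientReplicationError,
)
from .io import AA_ALPHABET, RepertoireSample
from .stats import GroupTestResult, bh_adjust, mann_whitney_u, welch_t

WEIGHTINGS = ("clonotypes", "reads")


def _check_weighting(weighting: str) -> None:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")


@dataclass(frozen=True)
class Spectratype:
    sample_id: str
    weighting: str
    fractions: dict[int, float]  # CDR3 length (aa) -> fraction

    def mean_length(self) -> float:
        return float(sum(L * f for L, f in self.fractions.items()))


def length_spectratype(
    sample: RepertoireSample, weighting: str = "clonotypes"
) -> Spectratype:
    _check_weighting(weighting)
    if not sample.records:
        raise EmptyRepertoireError(f"sample {sample.sample_id!r} is empty")
    fractions: dict[int, float] = {}
    if weighting == "clonotypes":
        w = 1.0 / sample.n_clonotypes
        for r in sample.records:
            fractions[len(r.cdr3_aa)] = fractions.get(len(r.cdr3_aa), 0.0) + w
    else:
        for r in sample.records:
            fractions[len(r.cdr3_aa)] = fractions.get(len(r.cdr3_aa), 0.0) + r.frequency
    return Spectratype(
        sample_id=sample.sample_id,
        weighting=weighting,
        fractions=dict(sorted(fractions.items())),
    )


@dataclass
class LengthComparisonResult:
    """Per-length Mann-Whitney comparison plus the mean-length Welch t-test."""

    per_length: pd.DataFrame  # length, mean_a, mean_b, u, p, q
    mean_length_test: GroupTestResult
    mean_lengths_a: list[float] = field(default_factory=list)
    mean_lengths_b: list[float] = field(default_factory=list)


def compare_length_distributions(
    group_a: list[Spectratype], group_b: list[Spectratype]
) -> LengthComparisonResult:
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientReplicationError(
            "compare_length_distributions needs at least two samples per group"
        )
    lengths = sorted(
        set().union(*(s.fractions for s in group_a), *(s.fractions for s in group_b))
    )
    rows = []
    for L in lengths:
        xa = np.array([s.fractions.get(L, 0.0) for s in group_a])
        xb = np.array([s.fractions.get(L, 0.0) for s in group_b])
        res = mann_whitney_u(xa, xb)
        rows.append((L, xa.mean(), xb.mean(), res.statistic, res.pvalue))
    per_length = pd.DataFrame(rows, columns=["length", "mean_a", "mean_b", "u", "p"])
    per_length["q"] = bh_adjust(per_length["p"].to_numpy())
    mla = [s.mean_length() for s in group_a]
    mlb = [s.mean_length() for s in group_b]
    return LengthComparisonResult(
        per_length=per_length,
        mean_length_test=welch_t(mla, mlb),
        mean_lengths_a=mla,
        mean_lengths_b=mlb,
    )


@dataclass
class PositionalCompositionMatrix:
    """20 x L matrix of per-position amino-acid fractions (logo data)."""

    length: int
    weighting: str
    n_sequences: int
    matrix: pd.DataFrame  # index = amino acids A..Y, columns = positions 1..L


def positional_composition(
    samples: list[RepertoireSample], length: int, weighting: str = "clonotypes"
) -> PositionalCompositionMatrix:
    """Pooled positional composition of all CDR3s of the given length.

    Each contributing sample is weighted equally; within a sample, each
    clonotype counts once (``clonotypes``) or by its read frequency
    (``reads``). Positions are 1-based from the CDR3 N-terminus.
    """
    _check_weighting(weighting)
    aa_index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    per_sample = []
    n_sequences = 0
    for sample in samples:
        recs = [r for r in sample.records if len(r.cdr3_aa) == length]
        if not recs:
            continue
        n_sequences += len(recs)
        m = np.zeros((len(AA_ALPHABET), length))
        if weighting == "clonotypes":
            weights = np.ones(len(recs))
        else:
            weights = np.array([r.count for r in recs], dtype=float)
        weights = weights / weights.sum()
        for rec, w in zip(recs, weights):
            for pos, aa in enumerate(rec.cdr3_aa):
                m[aa_index[aa], pos] += w
        per_sample.append(m)
    if not per_sample:
        raise EmptySelectionError(f"no CDR3 of length {length} in any sample")
    pooled = np.mean(per_sample, axis=0)
    matrix = pd.DataFrame(
        pooled, index=list(AA_ALPHABET), columns=range(1, length + 1)
    )
    return PositionalCompositionMatrix(
        length=length, weighting=weighting, n_sequences=n_sequences, matrix=matrix
    )


def modal_length_window(spectratypes: list[Spectratype], k: int) -> list[int]:
    """The k CDR3 lengths with the highest mean fraction across samples.

    Returned in decreasing order of mean fraction; exact ties break toward
    the shorter length.
    """
    if k < 1:
        raise BoundsError("k must be >= 1")
    lengths = sorted(set().union(*(s.fractions for s in spectratypes)))
    if k > len(lengths):
        raise BoundsError(f"k={k} exceeds the {len(lengths)} observed lengths")
    means = {
        L: float(np.mean([s.fractions.get(L, 0.0) for s in spectratypes]))
        for L in lengths
    }
    ranked = sorted(means, key=lambda L: (-means[L], L))
    return ranked[:k]
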
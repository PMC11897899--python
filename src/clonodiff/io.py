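"""Reading, validation and writing of clonotype tables.

The interchange format is the AIRR Rearrangement TSV dialect: one row per
clonotype with ``v_call``, ``j_call``, ``junction_aa`` (or ``cdr3_aa``) and
``duplicate_count`` (or ``count``) columns, plus an optional ``sample_id``
column for multi-sample files. Counts are authoritative: any frequency
column present in the input is ignored for computation and recomputed as
count / total_reads (a warning is logged when the two disagree).

Clonotypes are keyed at the amino-acid level by ``(v_call, j_call,
cdr3_aa)`` by default; rows sharing a key are merged by summing counts.
Nucleotide-level keying (adding ``cdr3_nt``) is available via
``key_nt=True``. The CDR3 string is taken exactly as given in the input
column — no trimming of the conserved anchor residues is attempted, because
upstream pipelines differ in whether they include them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .errors import (
    EmptyRepertoireError,
    FormatError,
    GeneNameError,
    LocusMismatchError,
)

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

LOCI = ("TRB", "IGH")
GROUPS = ("non_ORR", "ORR")

_LOCUS_PREFIXES = ("TRBV", "TRBD", "TRBJ", "IGHV", "IGHD", "IGHJ")

#: column aliases accepted on input, in priority order
_CDR3_COLUMNS = ("junction_aa", "cdr3_aa")
_COUNT_COLUMNS = ("duplicate_count", "count")

FREQ_TOL = 1e-9


class NormalizedGene(NamedTuple):
    """A normalized gene name plus whether the raw call was ambiguous."""

    name: str
    ambiguous: bool

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def normalize_gene_name(raw: str) -> NormalizedGene:
    """Normalize an IMGT-style gene call.

    Strips the allele suffix (``*NN``), trims whitespace and upper-cases the
    locus prefix. Ambiguous multi-gene calls (``TRBV12-3/12-4``) resolve to
    the first listed gene with the ``ambiguous`` flag set.

    Raises
    ------
    GeneNameError
        If the string carries no recognizable locus prefix
        (TRBV/TRBD/TRBJ/IGHV/IGHD/IGHJ).
    """
    name = raw.strip()
    if not name:
        raise GeneNameError("empty gene name")
    ambiguous = "/" in name
    if ambiguous:
        name = name.split("/", 1)[0].strip()
    name = name.split("*", 1)[0].strip()
    if len(name) >= 4:
        name = name[:4].upper() + name[4:]
    if not name.startswith(_LOCUS_PREFIXES):
        raise GeneNameError(
            f"gene name {raw!r} has no recognizable locus prefix "
            f"(expected one of {', '.join(_LOCUS_PREFIXES)})"
        )
    return NormalizedGene(name, ambiguous)


def _check_locus(gene: str, locus: str, segment: str, where: str) -> None:
    if gene and not gene.startswith(locus):
        raise LocusMismatchError(
            f"{where}: {segment} call {gene!r} does not match declared locus {locus!r}"
        )


@dataclass(frozen=True)
class ClonotypeRecord:
    """One rearrangement clonotype within a sample."""

    sample_id: str
    locus: str
    v_call: str
    j_call: str
    cdr3_aa: str
    count: int
    frequency: float = 0.0
    d_call: str = ""
    cdr3_nt: str = ""
    v_ambiguous: bool = False
    j_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise FormatError(f"unknown locus {self.locus!r}")
        if self.count < 1:
            raise FormatError(
                f"clonotype count must be >= 1, got {self.count} "
                f"(sample {self.sample_id})"
            )
        if not self.cdr3_aa or not _AA_SET.issuperset(self.cdr3_aa):
            bad = set(self.cdr3_aa) - _AA_SET
            raise FormatError(
                f"CDR3 {self.cdr3_aa!r} contains non-canonical symbols {sorted(bad)} "
                f"(sample {self.sample_id})"
            )
        _check_locus(self.v_call, self.locus, "V", f"sample {self.sample_id}")
        _check_locus(self.j_call, self.locus, "J", f"sample {self.sample_id}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_call, self.j_call, self.cdr3_aa)

    @property
    def key_nt(self) -> tuple[str, str, str, str]:
        return (self.v_call, self.j_call, self.cdr3_aa, self.cdr3_nt)


@dataclass
class RepertoireSample:
    """A patient's clonotype set with normalized read frequencies."""

    sample_id: str
    locus: str
    records: list[ClonotypeRecord]
    group: str | None = None
    total_reads: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyRepertoireError(f"sample {self.sample_id!r} has no clonotypes")
        self._renormalize()

    def _renormalize(self) -> None:
        self.total_reads = sum(r.count for r in self.records)
        self.records = [
            replace(r, frequency=r.count / self.total_reads) for r in self.records
        ]

    @property
    def n_clonotypes(self) -> int:
        return len(self.records)

    def frequencies(self) -> list[float]:
        return [r.frequency for r in self.records]


def merge_duplicates(
    records: Iterable[ClonotypeRecord], key_nt: bool = False
) -> list[ClonotypeRecord]:
    """Merge records sharing a clonotype key by summing counts."""
    merged: dict[tuple, ClonotypeRecord] = {}
    for rec in records:
        k = rec.key_nt if key_nt else rec.key
        if k in merged:
            prev = merged[k]
            merged[k] = replace(prev, count=prev.count + rec.count)
        else:
            merged[k] = rec
    return list(merged.values())


@dataclass(frozen=True)
class StudyDesign:
    """Mapping of sample ids to exactly two comparison groups."""

    groups: Mapping[str, str]
    locus: str
    group_labels: tuple[str, str] = GROUPS

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if labels != set(self.group_labels):
            raise FormatError(
                f"study design must use exactly the two group labels "
                f"{self.group_labels}, got {sorted(labels)}"
            )

    def samples_in(self, label: str) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == label)

    def assign(self, samples: list[RepertoireSample]) -> list[RepertoireSample]:
        """Attach group labels; raise listing orphans on any mismatch."""
        design_ids = set(self.groups)
        sample_ids = {s.sample_id for s in samples}
        orphans = sorted(design_ids ^ sample_ids)
        if orphans:
            raise FormatError(
                "design/sample mismatch; unmatched ids: " + ", ".join(orphans)
            )
        for s in samples:
            s.group = self.groups[s.sample_id]
        return samples


# ---------------------------------------------------------------------------
# TSV reading / writing


def _pick_column(columns: Iterable[str], candidates: tuple[str, ...]) -> str | None:
    cols = set(columns)
    for c in candidates:
        if c in cols:
            return c
    return None


def read_airr_tsv(
    path: str | Path,
    locus: str,
    *,
    key_nt: bool = False,
    column_overrides: Mapping[str, str] | None = None,
) -> list[RepertoireSample]:
    """Read clonotype tables from an AIRR Rearrangement-style TSV.

    One file may hold one sample (no ``sample_id`` column: the file stem is
    used) or several (``sample_id`` column present). Duplicate clonotypes
    are merged and frequencies recomputed from counts.

    ``column_overrides`` maps canonical names (``v_call``, ``j_call``,
    ``cdr3_aa``, ``count``, ``sample_id``) to the column names actually
    present in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    over = dict(column_overrides or {})

    def col(canonical: str, candidates: tuple[str, ...]) -> str | None:
        if canonical in over:
            if over[canonical] not in df.columns:
                raise FormatError(
                    f"{path}: configured column {over[canonical]!r} for "
                    f"{canonical!r} not found"
                )
            return over[canonical]
        return _pick_column(df.columns, candidates)

    v_col = col("v_call", ("v_call",))
    j_col = col("j_call", ("j_call",))
    cdr3_col = col("cdr3_aa", _CDR3_COLUMNS)
    count_col = col("count", _COUNT_COLUMNS)
    for name, c in (("v_call", v_col), ("j_call", j_col),
                    ("junction_aa/cdr3_aa", cdr3_col),
                    ("duplicate_count/count", count_col)):
        if c is None:
            raise FormatError(f"{path}: missing mandatory column {name!r}")

    sample_col = col("sample_id", ("sample_id", "repertoire_id"))
    d_col = _pick_column(df.columns, ("d_call",))
    nt_col = _pick_column(df.columns, ("junction", "cdr3", "cdr3_nt"))
    freq_col = _pick_column(df.columns, ("frequency", "duplicate_frequency"))

    records: dict[str, list[ClonotypeRecord]] = {}
    input_freqs: dict[str, list[float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        raw_count = row[count_col]
        try:
            count = int(raw_count)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}, line {i}: malformed count {raw_count!r}"
            ) from None
        sample_id = str(row[sample_col]) if sample_col else path.stem
        try:
            v = normalize_gene_name(row[v_col])
            j = normalize_gene_name(row[j_col])
        except GeneNameError as e:
            raise FormatError(f"{path}, line {i}: {e}") from None
        d_raw = row.get(d_col, "") if d_col else ""
        d_name = normalize_gene_name(d_raw).name if d_raw else ""
        try:
            rec = ClonotypeRecord(
                sample_id=sample_id,
                locus=locus,
                v_call=v.name,
                j_call=j.name,
                d_call=d_name,
                cdr3_aa=str(row[cdr3_col]),
                cdr3_nt=str(row.get(nt_col, "")) if nt_col else "",
                count=count,
                v_ambiguous=v.ambiguous,
                j_ambiguous=j.ambiguous,
            )
        except (FormatError, LocusMismatchError) as e:
            raise type(e)(f"{path}, line {i}: {e}") from None
        records.setdefault(sample_id, []).append(rec)
        if freq_col and row.get(freq_col):
            try:
                input_freqs.setdefault(sample_id, []).append(float(row[freq_col]))
            except ValueError:
                pass

    if not records:
        raise EmptyRepertoireError(f"{path}: no usable clonotype rows")

    samples = []
    for sample_id in records:
        merged = merge_duplicates(records[sample_id], key_nt=key_nt)
        sample = RepertoireSample(sample_id=sample_id, locus=locus, records=merged)
        freqs = input_freqs.get(sample_id)
        if freqs and abs(sum(freqs) - 1.0) > 1e-6:
            logger.warning(
                "%s: input frequency column for sample %s sums to %.6f; "
                "frequencies recomputed from counts",
                path, sample_id, sum(freqs),
            )
        samples.append(sample)
    return sorted(samples, key=lambda s: s.sample_id)


_AIRR_COLUMNS = (
    "sample_id", "locus", "v_call", "d_call", "j_call",
    "junction_aa", "duplicate_count", "frequency",
)


def write_airr_tsv(samples: Iterable[RepertoireSample], path: str | Path) -> Path:
    """Write samples to one AIRR-style TSV; round-trips exactly through
    :func:`read_airr_tsv` on (v_call, j_call, cdr3_aa, count)."""
    path = Path(path)
    rows = []
    for s in samples:
        total = sum(r.count for r in s.records)
        for r in s.records:
            rows.append(
                (s.sample_id, s.locus, r.v_call, r.d_call, r.j_call,
                 r.cdr3_aa, r.count, f"{r.count / total:.10g}")
            )
    df = pd.DataFrame(rows, columns=_AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_study_design(path: str | Path, locus: str) -> StudyDesign:
    """Read a two-column (sample_id, group) design TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("sample_id", "group"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {c!r}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"{path}: duplicated sample ids: {', '.join(dups)}")
    return StudyDesign(groups=dict(zip(df["sample_id"], df["group"])), locus=locus)


def write_study_design(design: StudyDesign, path: str | Path) -> Path:
    path = Path(path)
    rows = sorted(design.groups.items())
    pd.DataFrame(rows, columns=["sample_id", "group"]).to_csv(
        path, sep="\t", index=False
    )
    return path
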
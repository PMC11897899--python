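"""Bundled gene-segment universes for the human TRB and IGH loci.

Static lists of functional V and J segment names (IMGT-style nomenclature,
allele suffixes stripped), bundled so the simulator needs no external
reference download. The lists cover the functional repertoire commonly
reported by clonotype-calling pipelines; orphons and pseudogenes are
omitted on purpose — the simulator models expressed rearrangements.
"""

from __future__ import annotations

TRBV_GENES: tuple[str, ...] = (
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV4-2", "TRBV4-3",
    "TRBV5-1", "TRBV5-4", "TRBV5-5", "TRBV5-6", "TRBV5-8",
    "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV6-4", "TRBV6-5",
    "TRBV6-6", "TRBV6-8", "TRBV6-9", "TRBV7-2", "TRBV7-3",
    "TRBV7-4", "TRBV7-6", "TRBV7-7", "TRBV7-8", "TRBV7-9",
    "TRBV9", "TRBV10-1", "TRBV10-2", "TRBV10-3", "TRBV11-1",
    "TRBV11-2", "TRBV11-3", "TRBV12-3", "TRBV12-4", "TRBV12-5",
    "TRBV13", "TRBV14", "TRBV15", "TRBV16", "TRBV18",
    "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV29-1", "TRBV30",
)

TRBJ_GENES: tuple[str, ...] = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)

TRBD_GENES: tuple[str, ...] = ("TRBD1", "TRBD2")

IGHV_GENES: tuple[str, ...] = (
    "IGHV1-2", "IGHV1-3", "IGHV1-8", "IGHV1-18", "IGHV1-24",
    "IGHV1-45", "IGHV1-46", "IGHV1-58", "IGHV1-69", "IGHV2-5",
    "IGHV2-26", "IGHV2-70", "IGHV3-7", "IGHV3-9", "IGHV3-11",
    "IGHV3-13", "IGHV3-15", "IGHV3-20", "IGHV3-21", "IGHV3-23",
    "IGHV3-30", "IGHV3-33", "IGHV3-43", "IGHV3-48", "IGHV3-49",
    "IGHV3-53", "IGHV3-64", "IGHV3-66", "IGHV3-72", "IGHV3-73",
    "IGHV3-74", "IGHV4-4", "IGHV4-28", "IGHV4-31", "IGHV4-34",
    "IGHV4-39", "IGHV4-59", "IGHV4-61", "IGHV5-51", "IGHV6-1",
)

IGHJ_GENES: tuple[str, ...] = (
    "IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6",
)

IGHD_GENES: tuple[str, ...] = (
    "IGHD1-1", "IGHD2-2", "IGHD3-3", "IGHD3-10", "IGHD3-22",
    "IGHD4-17", "IGHD5-12", "IGHD6-13", "IGHD6-19",
)


def v_genes(locus: str) -> tuple[str, ...]:
    return TRBV_GENES if locus == "TRB" else IGHV_GENES


def j_genes(locus: str) -> tuple[str, ...]:
    return TRBJ_GENES if locus == "TRB" else IGHJ_GENES
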
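import pytest

from clonodiff.io import ClonotypeRecord, RepertoireSample


def make_sample(
    clonotypes,
    sample_id="S1",
    locus="TRB",
    group=None,
):
    """Build a RepertoireSample from (v, j, cdr3, count) tuples."""
    records = [
        ClonotypeRecord(
            sample_id=sample_id, locus=locus, v_call=v, j_call=j,
            cdr3_aa=cdr3, count=count,
        )
        for v, j, cdr3, count in clonotypes
    ]
    return RepertoireSample(
        sample_id=sample_id, locus=locus, records=records, group=group
    )


@pytest.fixture
def trb_sample():
    """Three TRB clonotypes with lengths 14, 14, 15 and counts 10, 10, 10."""
    return make_sample(
        [
            ("TRBV20-1", "TRBJ2-7", "CASSLGQGAYEQYF", 10),
            ("TRBV12-3", "TRBJ2-1", "CASSFSGTNEQFFF", 10),
            ("TRBV28", "TRBJ1-2", "CASSLAGGYGYTFGF", 10),
        ]
    )
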
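import pytest

import srnaproto as sp

#: truth-recovery conditions: full read-through, no background, no
#: enrichment — every emitted read is an exact annotated miRNA sequence.
CLEAN_PROFILE = sp.ProtocolProfile(
    name="clean",
    modal_length=22,
    star_enrichment=1.0,
    unannotated_fraction=0.0,
    repeat_fraction=0.0,
    adapter=sp.synthio.ILLUMINA_ADAPTER,
    readthrough_prob=1.0,
)


@pytest.fixture(scope="session")
def reference():
    return sp.make_reference(seed=1)


@pytest.fixture(scope="session")
def genome_index(reference):
    return reference.genome_index()


@pytest.fixture(scope="session")
def clean_library(reference):
    truth = sp.make_truth(reference, 1500, seed=5)
    return sp.simulate_library(
        reference, truth, CLEAN_PROFILE, seed=7, library_id="clean"
    ), truth


@pytest.fixture(scope="session")
def clean_alignments(reference, genome_index, clean_library):
    lib, _ = clean_library
    trimmed, _ = sp.trim_library(lib.reads, CLEAN_PROFILE.adapter)
    records, unaligned = sp.align_reads(
        [(t.read_id, t.sequence) for t in trimmed], genome_index
    )
    assert unaligned == 0
    return records
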
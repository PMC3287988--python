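"""Repeat-class profiling and consensus coverage."""

import numpy as np
import pandas as pd
import pytest

import srnaproto as sp
from srnaproto.core import AlignmentRecord, GenomicInterval
from srnaproto.repeats import (
    RepeatIndex,
    RepeatInstance,
    assign_repeat_class,
    assign_repeat_reads,
    class_profile,
    consensus_coverage,
    filter_repeat_reads,
)


def _aln(start, end, read_id="r", hits=1, strand="+"):
    return AlignmentRecord(
        read_id=read_id,
        interval=GenomicInterval("chr1", start, end, strand),
        mismatches=0,
        total_hits=hits,
        read_length=end - start,
    )


PRE_MIRNAS = [GenomicInterval("chr1", 500, 580, "+")]


def test_read_with_any_pre_mirna_hit_removed_entirely():
    records = [
        _aln(510, 532, read_id="x", hits=2),      # inside the pre-miRNA
        _aln(9000, 9022, read_id="x", hits=2),    # second placement elsewhere
        _aln(9100, 9122, read_id="y"),
    ]
    kept = filter_repeat_reads(records, PRE_MIRNAS)
    assert {r.read_id for r in kept} == {"y"}


@pytest.mark.parametrize(
    "length,hits,expected",
    [(22, 1, True), (27, 1, False), (18, 1, False),
     (22, 5000, True), (22, 5001, False)],
)
def test_length_and_hit_cap_filters(length, hits, expected):
    rec = _aln(9000, 9000 + length, hits=hits)
    kept = filter_repeat_reads([rec], PRE_MIRNAS)
    assert bool(kept) is expected


INSTANCES = [
    RepeatInstance(GenomicInterval("chr1", 1000, 7000, "+"), "LINE", "L1_a"),
    RepeatInstance(GenomicInterval("chr1", 8000, 8075, "+"), "tRNA", "t1"),
    RepeatInstance(GenomicInterval("chr1", 8200, 8350, "-"), "RNA", "r1"),
]


def test_containment_with_slack():
    index = RepeatIndex(INSTANCES)
    assert assign_repeat_class(_aln(3000, 3022), index) == {"LINE"}
    # 2 bp protrusion tolerated, 3 bp is not
    assert assign_repeat_class(_aln(6980, 7002), index) == {"LINE"}
    assert assign_repeat_class(_aln(6981, 7003), index) == set()


def test_random_assignments_match_all_pairs_containment_oracle():
    rng = np.random.default_rng(55)
    index = RepeatIndex(INSTANCES)
    for _ in range(500):
        start = int(rng.integers(0, 9000))
        n = int(rng.integers(19, 27))
        aln = _aln(start, start + n)
        expected = {
            inst.repeat_class
            for inst in INSTANCES
            if start >= inst.interval.start - 2 and start + n <= inst.interval.end + 2
        }
        assert assign_repeat_class(aln, index) == expected


def test_multi_class_read_counted_once_per_class():
    nested = INSTANCES + [
        RepeatInstance(GenomicInterval("chr1", 1000, 7000, "+"), "other", "ov"),
        RepeatInstance(GenomicInterval("chr1", 2900, 3100, "+"), "LINE", "L1_b"),
    ]
    index = RepeatIndex(nested)
    cpr, lpr = assign_repeat_reads([_aln(3000, 3022)], index)
    assert cpr["r"] == {"LINE", "other"}  # LINE once despite two instances


def test_toy_profile_matches_hand_computation():
    classes_per_read = {
        **{f"a{i}": {"LINE"} for i in range(10)},
        **{f"b{i}": {"tRNA"} for i in range(6)},
        "c0": {"RNA", "LINE"},
    }
    lengths = {rid: 22 for rid in classes_per_read}
    instances = pd.Series({"LINE": 5, "tRNA": 3, "RNA": 2})
    profile = class_profile(classes_per_read, lengths, instances)
    # LINE: 11 reads / 5 instances, tRNA: 6/3, RNA: 1/2
    assert profile.full.loc["LINE", "mean_coverage"] == pytest.approx(2.2)
    assert profile.full.loc["tRNA", "mean_coverage"] == pytest.approx(2.0)
    assert profile.full.loc["RNA", "mean_coverage"] == pytest.approx(0.5)
    assert profile.full["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
    assert profile.highlighted["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
    assert set(profile.highlighted.index) == {"LINE"}
    assert profile.length_histograms.loc["LINE", 22] == 11


def test_reads_without_instances_rejected():
    with pytest.raises(ValueError, match="instances"):
        class_profile({"r": {"LINE"}}, {"r": 22}, pd.Series({"tRNA": 3}))


def test_single_read_coverage_window(reference):
    seq = reference.consensus["L1_syn"][100:122]
    cov = consensus_coverage([("r", seq)], "L1_syn",
                             reference.consensus["L1_syn"])
    assert cov.sense[100:122].sum() == 22
    assert cov.sense.sum() == 22 and cov.antisense.sum() == 0
    assert cov.length_histogram[22] == 1


def test_depth_conservation_identity(reference):
    reads, _ = sp.simulate_consensus_reads(reference, "L1_syn", seed=2)
    cov = consensus_coverage(reads, "L1_syn", reference.consensus["L1_syn"])
    total_len = sum(len(s) for _, s in reads)
    assert cov.total_depth == total_len  # unique consensus: 1 placement/read


def test_planted_promoter_hotspot_recovered(reference):
    reads, _ = sp.simulate_consensus_reads(
        reference, "L1_syn", seed=4,
        n_promoter_sense=150, n_promoter_antisense=150, n_orf_sense=300,
    )
    cov = consensus_coverage(reads, "L1_syn", reference.consensus["L1_syn"])
    p_end = reference.consensus_regions["L1_syn"]["promoter"][1]
    assert cov.antisense[:p_end].sum() > 0
    assert cov.antisense[p_end:].sum() == 0
    assert cov.sense[p_end:].sum() > 0


def test_profile_reads_never_overlap_pre_mirnas(reference, clean_alignments):
    pre = [iv for _, iv in reference.pre_mirnas]
    kept = filter_repeat_reads(clean_alignments, pre)
    for rec in kept:
        assert all(rec.interval.overlap(iv) == 0 for iv in pre)


def test_empty_consensus_rejected():
    with pytest.raises(ValueError):
        consensus_coverage([], "x", "")
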
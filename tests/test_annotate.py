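"""Category assignment and miRNA counting rules, checked rule-by-rule."""

import numpy as np
import pandas as pd
import pytest

import srnaproto as sp
from srnaproto.annotate import (
    FeatureIndex,
    assign_category,
    count_mirnas,
    detection_summary,
    tally_categories,
)
from srnaproto.core import (
    CATEGORY_PRIORITY,
    AlignmentRecord,
    FeatureRecord,
    GenomicInterval,
    MatureMiRNARecord,
)


def _aln(start, end, read_id="r", strand="+", hits=1, chrom="chr1"):
    return AlignmentRecord(
        read_id=read_id,
        interval=GenomicInterval(chrom, start, end, strand),
        mismatches=0,
        total_hits=hits,
        read_length=end - start,
    )


def _feat(start, end, cls, name="f", strand="+"):
    return FeatureRecord(GenomicInterval("chr1", start, end, strand), cls, name)


def test_priority_microrna_beats_line():
    index = FeatureIndex(
        [_feat(100, 200, "microRNA"), _feat(0, 5000, "LINE")]
    )
    assert assign_category(_aln(120, 142), index) == "microRNA"


def test_overlap_below_seventy_percent_is_unannotated():
    # 15 of 22 bases inside the exon = 68.2%
    index = FeatureIndex([_feat(107, 400, "exon")])
    assert assign_category(_aln(100, 122), index) == "unannotated"
    # 16 of 22 = 72.7% qualifies
    index = FeatureIndex([_feat(106, 400, "exon")])
    assert assign_category(_aln(100, 122), index) == "exon"


def test_random_assignments_match_all_pairs_oracle():
    rng = np.random.default_rng(23)
    classes = list(CATEGORY_PRIORITY)
    features = [
        _feat(int(a), int(a) + int(rng.integers(20, 400)),
              classes[int(rng.integers(len(classes)))], f"f{i}")
        for i, a in enumerate(rng.integers(0, 5000, size=120))
    ]
    index = FeatureIndex(features)
    rank = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    for start in rng.integers(0, 5000, size=1000):
        n = int(rng.integers(19, 27))
        aln = _aln(int(start), int(start) + n)
        # oracle: score every (read, feature) pair directly
        qualifying = [
            f.feature_class
            for f in features
            if (min(aln.interval.end, f.interval.end)
                - max(aln.interval.start, f.interval.start)) / n >= 0.7
        ]
        expected = (
            min(qualifying, key=lambda c: rank[c]) if qualifying else "unannotated"
        )
        assert assign_category(aln, index) == expected


def test_adding_lower_priority_feature_never_changes_assignment():
    base = [_feat(100, 200, "other ncRNA")]
    aln = _aln(110, 132)
    before = assign_category(aln, FeatureIndex(base))
    after = assign_category(
        aln, FeatureIndex(base + [_feat(90, 300, "gene"), _feat(0, 400, "LINE")])
    )
    assert before == after == "other ncRNA"


def test_tally_conservation_and_multimapper_single_count(clean_alignments, reference):
    tally = tally_categories(clean_alignments, reference.feature_index())
    series = tally.as_series()
    assert series.sum() == tally.total_aligned
    assert tally.total_aligned == len({r.read_id for r in clean_alignments})


# --- miRNA counting ---------------------------------------------------------

MIRNAS = {
    "one-copy": MatureMiRNARecord(
        "one-copy", "mature", [GenomicInterval("chr1", 1000, 1022, "+")]
    ),
    "two-copy": MatureMiRNARecord(
        "two-copy",
        "mature",
        [
            GenomicInterval("chr1", 2000, 2022, "+"),
            GenomicInterval("chr1", 3000, 3022, "+"),
        ],
    ),
}


@pytest.mark.parametrize(
    "aln,species,expected",
    [
        (_aln(1000, 1022), "one-copy", 1),  # exact match
        (_aln(1002, 1024), "one-copy", 1),  # +2 bp at both ends: allowed
        (_aln(1003, 1022), "one-copy", 0),  # 3 bp offset at the 5' end
        (_aln(1000, 1025), "one-copy", 0),  # 3 bp at the 3' end
        (_aln(1000, 1022, strand="-"), "one-copy", 0),  # wrong strand
        (_aln(1000, 1022, hits=2), "one-copy", 0),  # 2 hits > 1 copy
        (_aln(2000, 2022, hits=2), "two-copy", 1),  # 2 hits <= 2 copies
        (_aln(2000, 2022, hits=3), "two-copy", 0),
        (_aln(1000, 1018), "one-copy", 0),  # 18 nt: below length range
        (_aln(1000, 1027), "one-copy", 0),  # 27 nt: above length range
    ],
)
def test_counting_rule_boundaries(aln, species, expected):
    counts = count_mirnas([aln], MIRNAS)
    assert counts[species] == expected


def test_random_cases_match_rule_evaluation_oracle():
    rng = np.random.default_rng(77)
    names = sorted(MIRNAS)
    for case in range(500):
        copy = MIRNAS[names[int(rng.integers(2))]].intervals[0]
        ds, de = int(rng.integers(-4, 5)), int(rng.integers(-4, 5))
        strand = "+" if rng.random() < 0.8 else "-"
        hits = int(rng.integers(1, 4))
        start, end = copy.start + ds, copy.end + de
        if end - start < 15:
            continue
        aln = _aln(start, end, read_id=f"c{case}", strand=strand, hits=hits)
        counts = count_mirnas([aln], MIRNAS)
        for name, rec in MIRNAS.items():
            expected = 0
            if 19 <= aln.read_length <= 26 and hits <= rec.copy_count:
                for civ in rec.intervals:
                    if (
                        strand == civ.strand
                        and abs(start - civ.start) <= 2
                        and abs(end - civ.end) <= 2
                    ):
                        expected = 1
            assert counts[name] == expected, (case, name)


def test_read_counts_once_per_species_even_with_two_valid_copies():
    # same read placed at both copies of the two-copy species
    records = [
        _aln(2000, 2022, read_id="r", hits=2),
        _aln(3000, 3022, read_id="r", hits=2),
    ]
    assert count_mirnas(records, MIRNAS)["two-copy"] == 1


def test_zero_copy_annotation_rejected():
    bad = {"empty": MatureMiRNARecord("empty", "mature", [])}
    with pytest.raises(ValueError):
        count_mirnas([], bad)


def test_counting_is_order_independent(clean_alignments, reference):
    fwd = count_mirnas(clean_alignments, reference.matures)
    rev = count_mirnas(clean_alignments[::-1], reference.matures)
    assert (fwd == rev).all()


def test_clean_library_counts_recover_truth_exactly(
    clean_alignments, clean_library, reference
):
    lib, truth = clean_library
    counts = count_mirnas(clean_alignments, reference.matures)
    assert (counts == lib.realized_counts).all()
    for name, c in truth.items():
        assert counts[name] == c


def test_detection_summary_matches_hand_enumeration():
    cm = pd.DataFrame(
        {
            "L1": [5, 0, 1, 0, 2],
            "L2": [3, 0, 0, 0, 1],
            "L3": [9, 0, 2, 1, 4],
        },
        index=list("abcde"),
    )
    hist, frac_all = detection_summary(cm)
    # a: 3 libs, b: 0 (excluded), c: 2, d: 1, e: 3
    assert hist.tolist() == [1, 1, 1, 2]
    assert frac_all == pytest.approx(2 / 4)
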
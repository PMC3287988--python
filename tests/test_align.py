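"""Exhaustive aligner: best-stratum completeness against a triple-loop oracle."""

import numpy as np
import pytest

import srnaproto as sp
from srnaproto.align import GenomeIndex, align_read, align_reads, cap_hits
from srnaproto.core import AlignmentRecord, GenomicInterval, revcomp
from srnaproto.io import read_sam, write_sam


def oracle_align(seq, genome_dict, max_mm):
    """Pure-Python scan of every offset on both strands; minimal stratum."""
    hits = []
    for chrom, g in genome_dict.items():
        for probe, strand in ((seq, "+"), (revcomp(seq), "-")):
            for i in range(len(g) - len(seq) + 1):
                window = g[i : i + len(seq)]
                mm = sum(
                    1
                    for a, b in zip(probe, window)
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mm:
                    hits.append((chrom, i, strand, mm))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return sorted((c, i, s) for c, i, s, mm in hits if mm == best)


def _records_as_tuples(records):
    return sorted(
        (r.interval.chrom, r.interval.start, r.interval.strand) for r in records
    )


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(9)
    return {"c1": "".join(rng.choice(list("ACGT"), 1500)),
            "c2": "".join(rng.choice(list("ACGT"), 700))}


def test_random_reads_match_triple_loop_oracle(small_genome):
    idx = GenomeIndex(small_genome)
    rng = np.random.default_rng(17)
    for _ in range(60):
        chrom = "c1" if rng.random() < 0.7 else "c2"
        g = small_genome[chrom]
        n = int(rng.integers(16, 25))
        pos = int(rng.integers(0, len(g) - n))
        seq = list(g[pos : pos + n])
        for _ in range(int(rng.integers(0, 3))):  # up to 2 mutations
            seq[int(rng.integers(n))] = str(rng.choice(list("ACGT")))
        seq = "".join(seq)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        records = align_read("r", seq, idx, max_mismatches=2)
        assert _records_as_tuples(records) == oracle_align(seq, small_genome, 2)


def test_planted_unique_read_reports_annotated_locus(reference, genome_index):
    single = next(
        name
        for name, rec in sorted(reference.matures.items())
        if rec.copy_count == 1
    )
    iv = reference.matures[single].intervals[0]
    records = align_read("r", reference.mature_seqs[single], genome_index)
    assert len(records) == 1
    rec = records[0]
    assert (rec.interval, rec.mismatches, rec.total_hits) == (iv, 0, 1)


def test_two_copy_species_yields_two_best_hits(reference, genome_index):
    multi = next(
        name for name, rec in reference.matures.items() if rec.copy_count == 2
    )
    records = align_read("r", reference.mature_seqs[multi], genome_index)
    assert len(records) == 2
    assert {r.interval for r in records} == set(reference.matures[multi].intervals)
    assert all(r.total_hits == 2 for r in records)


def test_absent_read_returns_empty(genome_index):
    # a read of Ns matches nothing anywhere
    assert align_read("r", "N" * 22, genome_index) == []


def test_strand_symmetry(small_genome):
    idx = GenomeIndex(small_genome)
    seq = small_genome["c1"][100:122]
    fwd = align_read("r", seq, idx)
    rev = align_read("r", revcomp(seq), idx)
    flip = {"+": "-", "-": "+"}
    assert {
        (r.interval.chrom, r.interval.start, flip[r.interval.strand]) for r in fwd
    } == {(r.interval.chrom, r.interval.start, r.interval.strand) for r in rev}


def test_hit_count_equals_record_count(clean_alignments):
    by_read = sp.align.group_by_read(clean_alignments)
    for records in by_read.values():
        assert {r.total_hits for r in records} == {len(records)}


def test_invalid_reads_rejected(genome_index):
    with pytest.raises(ValueError):
        align_read("r", "ACGTXACGTACGTACGTACGT", genome_index)
    with pytest.raises(ValueError):
        align_read("r", "ACGT", genome_index)


def _fake_record(read_id, hits, start=0):
    return AlignmentRecord(
        read_id=read_id,
        interval=GenomicInterval("chr1", start, start + 22),
        mismatches=0,
        total_hits=hits,
        read_length=22,
    )


def test_cap_hits_inclusive_boundary():
    keep = _fake_record("keep", 5000)
    drop = _fake_record("drop", 5001)
    assert cap_hits([keep, drop]) == [keep]
    unique = _fake_record("u", 1)
    multi = [_fake_record("m", 2, s) for s in (0, 100)]
    assert cap_hits([keep, unique] + multi, max_hits=1) == [unique]


def test_sam_round_trip(tmp_path, clean_alignments, genome_index):
    subset = clean_alignments[:200]
    path = tmp_path / "out.sam"
    write_sam(path, subset, genome_index.lengths)
    back, skipped = read_sam(path)
    assert skipped == 0
    key = lambda r: (r.read_id, r.interval, r.mismatches, r.total_hits)
    assert sorted(map(key, back)) == sorted(map(key, subset))


def test_bed_import(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t100\t122\treadA\t0\t-\n")
    records = sp.io.alignments_from_bed(bed)
    assert len(records) == 1
    rec = records[0]
    assert rec.interval == GenomicInterval("chr1", 100, 122, "-")
    assert rec.total_hits == 1
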
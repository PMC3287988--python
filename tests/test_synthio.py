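"""Synthetic reference and library generator: planted-truth bookkeeping."""

import re

import numpy as np
import pandas as pd
import pytest

import srnaproto as sp
from tests.conftest import CLEAN_PROFILE


def test_mature_intervals_contained_in_parents(reference):
    pres = dict(reference.pre_mirnas)
    for name, rec in reference.matures.items():
        for idx, iv in enumerate(rec.intervals):
            assert 19 <= iv.length <= 24
            parent = pres[reference.mature_parents[(name, idx)]]
            assert parent.start <= iv.start and iv.end <= parent.end
            assert iv.strand == parent.strand


def test_annotations_lie_within_genome(reference):
    glen = len(reference.genome["chr1"])
    ivs = [iv for _, iv in reference.pre_mirnas]
    ivs += [f.interval for f in reference.features]
    ivs += [inst.interval for inst in reference.repeat_instances]
    assert all(0 <= iv.start < iv.end <= glen for iv in ivs)


def test_repeat_classes_from_closed_set(reference):
    classes = {inst.repeat_class for inst in reference.repeat_instances}
    assert classes <= set(sp.core.REPEAT_CLASSES)
    assert "LINE" in classes


def test_multicopy_species_copy_number_matches_regex_scan(reference):
    genome = reference.genome["chr1"]
    copies = reference.copy_numbers()
    assert (copies >= 1).all() and (copies == 2).any()
    for name in ["syn-miR-0", "syn-miR-0*", "syn-miR-1"]:
        seq = reference.mature_seqs[name]
        found = sum(
            len(re.findall(f"(?={re.escape(p)})", genome))
            for p in {seq, sp.revcomp(seq)}
        )
        assert found == copies[name]


def test_reference_requires_seed_and_minimum_sizes():
    with pytest.raises(ValueError):
        sp.make_reference(seed=None)
    with pytest.raises(ValueError):
        sp.make_reference(seed=1, genome_length=5000)
    with pytest.raises(ValueError):
        sp.make_reference(seed=1, n_mirnas=1)
    with pytest.raises(ValueError):  # plantings cannot fit
        sp.make_reference(seed=1, genome_length=10_000, n_repeat_instances=100)


def test_reference_serialisation_is_deterministic(tmp_path):
    paths_a = sp.make_reference(seed=3).write(tmp_path / "a")
    paths_b = sp.make_reference(seed=3).write(tmp_path / "b")
    for key in paths_a:
        assert paths_a[key].read_bytes() == paths_b[key].read_bytes()


def test_reference_round_trips_through_gff3(tmp_path, reference):
    paths = reference.write(tmp_path / "ref")
    pre, matures = sp.io.read_mirna_gff3(paths["mirna_gff3"])
    assert dict(pre) == dict(reference.pre_mirnas)
    for name, rec in reference.matures.items():
        assert sorted(matures[name].intervals) == sorted(rec.intervals)
        assert matures[name].arm == rec.arm


def test_library_bytes_identical_for_same_seed(tmp_path, reference):
    truth = sp.make_truth(reference, 500, seed=2)
    paths = []
    for sub in ("x", "y"):
        lib = sp.simulate_library(reference, truth, sp.IDT_LIKE, seed=9)
        p = tmp_path / f"{sub}.fastq"
        lib.write_fastq(p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_read_conservation_and_provenance_completeness(reference):
    truth = sp.make_truth(reference, 800, seed=4)
    lib = sp.simulate_library(reference, truth, sp.ILLUMINA_LIKE, seed=6)
    sources = lib.provenance["source"]
    n_ann = (~sources.str.startswith(("unannotated", "repeat:"))).sum()
    assert lib.n_reads == len(lib.provenance)
    assert n_ann == lib.realized_counts.sum()
    assert set(lib.provenance["read_id"]) == {rid for rid, _ in lib.reads}
    assert lib.provenance["read_id"].is_unique


def test_no_enrichment_emits_truth_exactly(reference):
    truth = sp.make_truth(reference, 600, seed=8)
    lib = sp.simulate_library(reference, truth, CLEAN_PROFILE, seed=10)
    for name, count in truth.items():
        assert lib.realized_counts[name] == count


def test_full_readthrough_reads_end_with_adapter_prefix(reference):
    truth = sp.make_truth(reference, 200, seed=1)
    lib = sp.simulate_library(reference, truth, CLEAN_PROFILE, seed=2)
    adapter = CLEAN_PROFILE.adapter
    for (_, seq), ins_len in zip(lib.reads, lib.provenance["insert_length"]):
        tail = seq[ins_len:]
        assert len(tail) > 0 and adapter.startswith(tail)


@pytest.mark.parametrize("mode", [22, 23])
def test_background_insert_length_mode_follows_profile(reference, mode):
    profile = sp.ProtocolProfile(
        name=f"m{mode}", modal_length=mode, length_sd=1.2,
        unannotated_fraction=0.85, adapter=sp.synthio.IDT_ADAPTER,
        readthrough_prob=1.0,
    )
    truth = sp.make_truth(reference, 1500, seed=3)  # ~8500 background reads
    lib = sp.simulate_library(reference, truth, profile, seed=11)
    planted = lib.provenance.query("source == 'unannotated'")["insert_length"]
    assert planted.value_counts().idxmax() == mode
    # trimmed lengths reproduce the planted histogram (read-through 1.0)
    trimmed, hist = sp.trim_library(lib.reads, profile.adapter)
    background_mode = hist.loc[list(range(19, 31))].idxmax()
    all_planted = lib.provenance["insert_length"].value_counts()
    assert background_mode == all_planted.idxmax() == mode


def test_unannotated_reads_avoid_all_features(reference):
    profile = sp.ProtocolProfile(
        name="bg", unannotated_fraction=0.5,
        adapter=sp.synthio.ILLUMINA_ADAPTER,
    )
    truth = sp.make_truth(reference, 400, seed=3)
    lib = sp.simulate_library(reference, truth, profile, seed=12)
    index = reference.feature_index()
    bg = lib.provenance.query("source == 'unannotated'")
    assert len(bg) > 0
    for row in bg.itertuples(index=False):
        assert index.overlapping(row.chrom, row.start, row.end) == []


def test_truth_with_unknown_species_rejected(reference):
    with pytest.raises(ValueError):
        sp.simulate_library(reference, {"nope": 5}, CLEAN_PROFILE, seed=1)


def test_profile_validation():
    with pytest.raises(ValueError):
        sp.ProtocolProfile(name="bad", star_enrichment=0.5)
    with pytest.raises(ValueError):
        sp.ProtocolProfile(name="bad", unannotated_fraction=1.5)
    with pytest.raises(ValueError):
        sp.ProtocolProfile(name="bad", adapter="ACGU")
    with pytest.raises(ValueError):
        sp.ProtocolProfile(name="bad", unannotated_fraction=0.6,
                           repeat_fraction=0.5)


def test_consensus_reads_respect_regions(reference):
    reads, truth = sp.simulate_consensus_reads(reference, "L1_syn", seed=5)
    promoter = reference.consensus_regions["L1_syn"]["promoter"]
    anti = truth.query("strand == '-'")
    assert (anti["region"] == "promoter").all()
    assert (anti["end"] <= promoter[1]).all()
    assert set(truth["read_id"]) == {rid for rid, _ in reads}
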
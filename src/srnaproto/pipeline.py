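"""End-to-end orchestration: config, staging, reports, manifest.

The pipeline composes trim -> align -> annotate -> quantify -> compare ->
repeats over a set of FASTQ libraries described by a single YAML config,
and writes every artifact as TSV/Newick plus a JSON manifest holding input
hashes, parameters and read-accounting totals. A rerun with the same
config and inputs is bit-identical (no stage uses randomness).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align, annotate, compare, io as sio, quantify, repeats, trim
from .repeats import RepeatInstance

log = logging.getLogger("srnaproto")


@dataclass
class LibraryConfig:
    library_id: str
    fastq: Path
    adapter: str
    group: str
    protocol: str


@dataclass
class RunConfig:
    seed: int
    genome: Path
    mirna_gff3: Path
    features_bed: Path
    repeats_bed: Path
    consensus_fasta: Path
    libraries: list[LibraryConfig]
    min_overlap: int = trim.DEFAULT_MIN_OVERLAP
    trim_max_mismatches: int = trim.DEFAULT_MAX_MISMATCHES
    align_max_mismatches: int = align.DEFAULT_MAX_MISMATCHES
    max_hits: int = align.DEFAULT_MAX_HITS
    mirna_length_range: tuple[int, int] = annotate.MIRNA_LENGTH_RANGE
    position_tolerance: int = annotate.POSITION_TOLERANCE
    tolerance_mode: str = "both"
    pseudocount: float = quantify.PSEUDOCOUNT
    alpha: float = quantify.ALPHA
    consensus_name: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        ref = raw["reference"]
        libs = [
            LibraryConfig(
                library_id=entry["id"],
                fastq=base / entry["fastq"],
                adapter=entry["adapter"],
                group=entry.get("group", "default"),
                protocol=entry.get("protocol", "unknown"),
            )
            for entry in raw["libraries"]
        ]
        params = raw.get("parameters", {})
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            genome=base / ref["genome"],
            mirna_gff3=base / ref["mirna_gff3"],
            features_bed=base / ref["features_bed"],
            repeats_bed=base / ref["repeats_bed"],
            consensus_fasta=base / ref["consensus_fasta"],
            libraries=libs,
            consensus_name=raw.get("consensus_name"),
            extra=params,
        )
        for key in (
            "min_overlap", "trim_max_mismatches", "align_max_mismatches",
            "max_hits", "position_tolerance", "tolerance_mode",
            "pseudocount", "alpha",
        ):
            if key in params:
                setattr(cfg, key, params[key])
        if "mirna_length_range" in params:
            cfg.mirna_length_range = tuple(params["mirna_length_range"])
        return cfg

    def validate(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("library ids must be unique")
        missing = [
            str(p)
            for p in [
                self.genome, self.mirna_gff3, self.features_bed,
                self.repeats_bed, self.consensus_fasta,
            ]
            + [lib.fastq for lib in self.libraries]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("loading reference")
    genome = align.GenomeIndex(sio.read_fasta(config.genome))
    pre_mirnas, matures = sio.read_mirna_gff3(config.mirna_gff3)
    feature_records = sio.features_from_bed(sio.read_bed6(config.features_bed))
    repeat_df = sio.read_bed6(config.repeats_bed)
    repeat_instances = []
    for row in repeat_df.itertuples(index=False):
        cls, name = (row.name.split("|", 1) + [row.name])[:2]
        from .core import GenomicInterval

        repeat_instances.append(
            RepeatInstance(
                GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                cls,
                name,
            )
        )
    consensus = sio.read_fasta(config.consensus_fasta)

    from .core import FeatureRecord

    category_features = [
        FeatureRecord(iv, "microRNA", pre_id) for pre_id, iv in pre_mirnas
    ]
    category_features += feature_records
    for inst in repeat_instances:
        cls = "LINE" if inst.repeat_class == "LINE" else "other repeat"
        category_features.append(FeatureRecord(inst.interval, cls, inst.name))
    feature_index = annotate.FeatureIndex(category_features)
    repeat_index = repeats.RepeatIndex(repeat_instances)
    pre_intervals = [iv for _, iv in pre_mirnas]

    align_cache: dict = {}
    length_hists: dict[str, pd.Series] = {}
    tallies: dict[str, pd.Series] = {}
    counts: dict[str, pd.Series] = {}
    accounting = {}
    class_profiles: dict[str, pd.DataFrame] = {}
    coverage_tables: dict[str, pd.DataFrame] = {}

    for lib in config.libraries:
        log.info("processing library %s", lib.library_id)
        raw_reads = list(sio.read_fastq(lib.fastq))
        trimmed, hist = trim.trim_library(
            raw_reads, lib.adapter, config.min_overlap, config.trim_max_mismatches
        )
        length_hists[lib.library_id] = hist
        records, unaligned = align.align_reads(
            list(trim.trimmed_sequences(trimmed)),
            genome,
            config.align_max_mismatches,
            cache=align_cache,
        )
        records = align.cap_hits(records, config.max_hits)
        tally = annotate.tally_categories(records, feature_index)
        tallies[lib.library_id] = tally.as_series()
        counts[lib.library_id] = annotate.count_mirnas(
            records,
            matures,
            config.mirna_length_range,
            config.position_tolerance,
            config.tolerance_mode,
        )
        accounting[lib.library_id] = {
            "reads_in": len(raw_reads),
            "reads_trimmed": int(sum(1 for t in trimmed if t.trimmed)),
            "reads_unaligned": int(unaligned),
            "reads_aligned": tally.total_aligned,
            "reads_annotated": int(
                tally.total_aligned - tally.counts.get("unannotated", 0)
            ),
        }
        repeat_recs = repeats.filter_repeat_reads(
            records, pre_intervals, max_hits=config.max_hits
        )
        classes_per_read, length_per_read = repeats.assign_repeat_reads(
            repeat_recs, repeat_index
        )
        if classes_per_read:
            profile = repeats.class_profile(
                classes_per_read, length_per_read, repeat_index.instance_counts()
            )
            class_profiles[lib.library_id] = profile.full
        if config.consensus_name and config.consensus_name in consensus:
            cov = repeats.consensus_coverage(
                list(trim.trimmed_sequences(trimmed)),
                config.consensus_name,
                consensus[config.consensus_name],
                config.align_max_mismatches,
            )
            coverage_tables[lib.library_id] = pd.DataFrame(
                {"position": range(len(cov.sense)), "sense": cov.sense,
                 "antisense": cov.antisense}
            )

    count_matrix = pd.DataFrame(counts)
    sio.write_matrix(outdir / "mirna_counts.tsv", count_matrix, "species")
    pd.DataFrame(length_hists).to_csv(outdir / "length_histograms.tsv", sep="\t",
                                      index_label="length")
    pd.DataFrame(tallies).to_csv(outdir / "category_tallies.tsv", sep="\t",
                                 index_label="category")

    factors = quantify.size_factors(count_matrix)
    normalized = quantify.glog_transform(count_matrix, factors)
    factors.to_csv(outdir / "size_factors.tsv", sep="\t", index_label="library")
    sio.write_matrix(outdir / "normalized.tsv", normalized, "species")

    corr = compare.correlation_matrix(count_matrix)
    sio.write_matrix(outdir / "correlation.tsv", corr, "library")
    dendro = compare.hierarchical_cluster(normalized)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    pairs = {
        name: name.rstrip("*")
        for name in count_matrix.index
        if name.endswith("*")
    }
    star_report = compare.star_ratio_report(count_matrix, pairs)
    star_report.table.to_csv(outdir / "star_ratios.tsv", sep="\t", index=False)

    groups = {lib.library_id: lib.group for lib in config.libraries}
    group_sizes = pd.Series(groups).value_counts()
    de_table = None
    if len(group_sizes) == 2 and (group_sizes >= 2).all():
        de = quantify.de_test(
            count_matrix, groups, factors, alpha=config.alpha,
            pseudocount=config.pseudocount,
        )
        de_table = de.table
        de_table.to_csv(outdir / "de_results.tsv", sep="\t", index_label="species")

    for lib_id, profile_df in class_profiles.items():
        profile_df.to_csv(outdir / f"repeat_profile.{lib_id}.tsv", sep="\t",
                          index_label="class")
    for lib_id, cov_df in coverage_tables.items():
        cov_df.to_csv(outdir / f"consensus_coverage.{lib_id}.tsv", sep="\t",
                      index=False)

    manifest = {
        "inputs": {
            "genome": _sha256(config.genome),
            "mirna_gff3": _sha256(config.mirna_gff3),
            "features_bed": _sha256(config.features_bed),
            "repeats_bed": _sha256(config.repeats_bed),
            "consensus_fasta": _sha256(config.consensus_fasta),
            "fastq": {
                lib.library_id: _sha256(lib.fastq) for lib in config.libraries
            },
        },
        "parameters": {
            "seed": config.seed,
            "min_overlap": config.min_overlap,
            "trim_max_mismatches": config.trim_max_mismatches,
            "align_max_mismatches": config.align_max_mismatches,
            "max_hits": config.max_hits,
            "mirna_length_range": list(config.mirna_length_range),
            "position_tolerance": config.position_tolerance,
            "tolerance_mode": config.tolerance_mode,
            "pseudocount": config.pseudocount,
            "alpha": config.alpha,
        },
        "accounting": accounting,
        "n_species": int(count_matrix.shape[0]),
        "n_differential": int((de_table["padj"] < config.alpha).sum())
        if de_table is not None
        else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
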
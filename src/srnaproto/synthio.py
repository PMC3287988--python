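"""Synthetic reference and protocol-biased read-library generator.

Everything downstream of sequencing is testable against planted ground
truth: a toy genome carries pre-miRNA hairpins (with mature and star arms,
including a multi-copy species), protein-coding genes with exons, small
ncRNAs, pseudogenes and repeat instances copied from class consensus
templates — among them an L1-like element with a designated promoter
sub-interval. Libraries are then sampled from a per-species truth table
under a protocol profile that sets the hallmarks of real protocol bias:
the modal insert length (22 vs 23 nt), the 3' adapter and its read-through
probability, a multiplicative miR* over-sampling factor, and a fraction of
reads drawn from feature-free genomic background ("unannotated" reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as sio
from .align import GenomeIndex
from .annotate import FeatureIndex
from .core import FeatureRecord, GenomicInterval, MatureMiRNARecord, revcomp
from .repeats import RepeatInstance

MIN_GENOME_LENGTH = 10_000
READ_LENGTH = 36  # raw sequencer read length before trimming
INSERT_RANGE = (19, 30)

#: 3' adapter sequences of the two emulated protocol families.
ILLUMINA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
IDT_ADAPTER = "CTGTAGGCACCATCAAT"

_CLASS_TEMPLATE_LENGTHS = {
    "RNA": 150,
    "rRNA": 120,
    "tRNA": 75,
    "snRNA": 100,
    "scRNA": 90,
    "srpRNA": 110,
    "other": 80,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ProtocolProfile:
    """Library-preparation bias bundle for one protocol."""

    name: str
    modal_length: int = 22  # modal insert length, nt
    length_sd: float = 1.5  # spread of the truncated discrete Gaussian
    star_enrichment: float = 1.0  # multiplicative miR* sampling weight
    unannotated_fraction: float = 0.0  # fraction of reads from background
    repeat_fraction: float = 0.0  # fraction of reads from repeat instances
    adapter: str = ILLUMINA_ADAPTER
    readthrough_prob: float = 1.0  # chance the read runs into the adapter

    def __post_init__(self) -> None:
        if not (0.0 <= self.unannotated_fraction <= 1.0):
            raise ValueError("unannotated_fraction must be in [0, 1]")
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise ValueError("repeat_fraction must be in [0, 1]")
        if self.unannotated_fraction + self.repeat_fraction >= 1.0:
            raise ValueError("unannotated + repeat fractions must leave room "
                             "for annotated reads")
        if not (0.0 <= self.readthrough_prob <= 1.0):
            raise ValueError("readthrough_prob must be in [0, 1]")
        if not np.isfinite(self.star_enrichment) or self.star_enrichment < 1.0:
            raise ValueError("star_enrichment must be finite and >= 1")
        if not self.adapter or set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be a non-empty ACGT string")
        if not (INSERT_RANGE[0] <= self.modal_length <= INSERT_RANGE[1]):
            raise ValueError("modal_length must lie in the insert range")


#: Study-condition profiles: an Illumina-adapter-like protocol peaking at
#: 22 nt, and an IDT-adapter-like protocol peaking at 23 nt with strong
#: miR* over-capture and a larger unannotated background.
ILLUMINA_LIKE = ProtocolProfile(
    name="illumina_like",
    modal_length=22,
    length_sd=1.2,
    star_enrichment=1.0,
    unannotated_fraction=0.2,
    repeat_fraction=0.1,
    adapter=ILLUMINA_ADAPTER,
    readthrough_prob=0.95,
)
IDT_LIKE = ProtocolProfile(
    name="idt_like",
    modal_length=23,
    length_sd=1.2,
    star_enrichment=5.0,
    unannotated_fraction=0.35,
    repeat_fraction=0.1,
    adapter=IDT_ADAPTER,
    readthrough_prob=0.95,
)


@dataclass
class ReferenceBundle:
    """In-memory toy reference; ``write`` serialises it to standard formats."""

    genome: dict[str, str]
    pre_mirnas: list[tuple[str, GenomicInterval]]
    matures: dict[str, MatureMiRNARecord]
    mature_parents: dict[tuple[str, int], str]
    mature_seqs: dict[str, str]
    features: list[FeatureRecord]
    repeat_instances: list[RepeatInstance]
    consensus: dict[str, str]
    consensus_regions: dict[str, dict[str, tuple[int, int]]]
    free_windows: list[tuple[str, int, int]]
    _genome_index: GenomeIndex | None = field(default=None, repr=False)

    def genome_index(self) -> GenomeIndex:
        if self._genome_index is None:
            self._genome_index = GenomeIndex(self.genome)
        return self._genome_index

    def copy_numbers(self) -> pd.Series:
        return pd.Series(
            {name: rec.copy_count for name, rec in sorted(self.matures.items())},
            name="copy_number",
        )

    def mirna_pairs(self) -> dict[str, str]:
        """star species name -> mature partner name."""
        return {
            name: name.rstrip("*")
            for name, rec in self.matures.items()
            if rec.arm == "star"
        }

    def feature_index(self) -> FeatureIndex:
        """Category features: pre-miRNAs (microRNA), annotated features,
        LINE and other repeat instances."""
        feats: list[FeatureRecord] = [
            FeatureRecord(iv, "microRNA", pre_id) for pre_id, iv in self.pre_mirnas
        ]
        feats.extend(self.features)
        for inst in self.repeat_instances:
            cls = "LINE" if inst.repeat_class == "LINE" else "other repeat"
            feats.append(FeatureRecord(inst.interval, cls, inst.name))
        return FeatureIndex(feats)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "mirna_gff3": outdir / "mirna.gff3",
            "features_bed": outdir / "features.bed",
            "repeats_bed": outdir / "repeats.bed",
            "consensus": outdir / "consensus.fa",
            "copy_numbers": outdir / "copy_numbers.tsv",
        }
        sio.write_fasta(paths["genome"], self.genome)
        sio.write_mirna_gff3(
            paths["mirna_gff3"], self.pre_mirnas, self.matures, self.mature_parents
        )
        sio.write_bed6(
            paths["features_bed"],
            [(f.interval, f"{f.feature_class}|{f.name}") for f in self.features],
        )
        sio.write_bed6(
            paths["repeats_bed"],
            [
                (inst.interval, f"{inst.repeat_class}|{inst.name}")
                for inst in self.repeat_instances
            ],
        )
        sio.write_fasta(paths["consensus"], self.consensus)
        self.copy_numbers().to_csv(paths["copy_numbers"], sep="\t", index_label="species")
        return paths


def _count_occurrences(genome: str, seq: str) -> int:
    """Overlapping occurrences of seq or its reverse complement."""
    total = 0
    for probe in {seq, revcomp(seq)}:
        start = 0
        while True:
            pos = genome.find(probe, start)
            if pos < 0:
                break
            total += 1
            start = pos + 1
    return total


def _length_probs(mode: int, sd: float, lo: int, hi: int) -> np.ndarray:
    lengths = np.arange(lo, hi + 1)
    probs = np.exp(-((lengths - mode) ** 2) / (2.0 * sd**2))
    return probs / probs.sum()


def sample_insert_lengths(
    rng: np.random.Generator, n: int, mode: int, sd: float,
    lo: int = INSERT_RANGE[0], hi: int = INSERT_RANGE[1],
) -> np.ndarray:
    """Truncated discrete Gaussian insert lengths on [lo, hi]."""
    return rng.choice(np.arange(lo, hi + 1), size=n, p=_length_probs(mode, sd, lo, hi))


def make_reference(
    seed: int,
    genome_length: int = 50_000,
    n_mirnas: int = 10,
    n_repeat_instances: int = 40,
    chrom: str = "chr1",
) -> ReferenceBundle:
    """Build a toy genome with planted miRNA, gene and repeat annotation.

    One miRNA locus is planted in two exact genomic copies so the
    copy-number counting rule is exercised. Repeat instances are copies of
    per-class consensus templates; the L1-like consensus contributes LINE
    instances covering its promoter and ORF regions. Raises if the planted
    copy-number bookkeeping does not match the realised genome.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if genome_length < MIN_GENOME_LENGTH:
        raise ValueError(f"genome_length must be >= {MIN_GENOME_LENGTH}")
    if n_mirnas < 2:
        raise ValueError("need at least two miRNA loci")
    rng = np.random.default_rng(seed)
    genome = list(rng.choice(_BASES, size=genome_length))

    # consensus sequences: an L1-like element plus one template per class
    l1_name = "L1_syn"
    l1_len, promoter_end = 3000, 600
    consensus = {l1_name: "".join(rng.choice(_BASES, size=l1_len))}
    regions = {l1_name: {"promoter": (0, promoter_end), "orf": (promoter_end, l1_len)}}
    templates = {
        cls: "".join(rng.choice(_BASES, size=ln))
        for cls, ln in _CLASS_TEMPLATE_LENGTHS.items()
    }

    # ---- plan loci -------------------------------------------------------
    plans: list[tuple[str, dict]] = []
    mature_lengths = 19 + rng.choice(6, size=n_mirnas, p=_length_probs(22, 1.3, 19, 24))
    star_lengths = 19 + rng.choice(6, size=n_mirnas, p=_length_probs(22, 1.3, 19, 24))
    for i in range(n_mirnas):
        plans.append(
            ("mirna", {"idx": i, "mature_len": int(mature_lengths[i]),
                       "star_len": int(star_lengths[i])})
        )
    plans.append(("mirna_copy", {"idx": 0}))  # second exact copy of locus 0

    n_line = max(2, n_repeat_instances // 10)
    other_classes = [c for c in _CLASS_TEMPLATE_LENGTHS]
    for i in range(n_line):
        # truncated L1 copies; the first ones retain the promoter region
        if i % 2 == 0:
            off, ln = 0, int(rng.integers(900, 1500))
        else:
            off = int(rng.integers(promoter_end, l1_len - 900))
            ln = int(rng.integers(700, min(1200, l1_len - off)))
        plans.append(("repeat_line", {"offset": off, "length": ln, "idx": i}))
    for i in range(n_repeat_instances - n_line):
        cls = other_classes[i % len(other_classes)]
        plans.append(("repeat", {"class": cls, "idx": i}))

    n_genes = 4
    for i in range(n_genes):
        plans.append(("gene", {"idx": i}))
    for i in range(3):
        plans.append(("ncrna", {"idx": i}))
    for i in range(2):
        plans.append(("pseudogene", {"idx": i}))

    def plan_length(kind: str, info: dict) -> int:
        if kind == "mirna":
            return info["mature_len"] + info["star_len"] + 15 + 16
        if kind == "mirna_copy":
            p = next(q for k, q in plans if k == "mirna" and q["idx"] == info["idx"])
            return p["mature_len"] + p["star_len"] + 15 + 16
        if kind == "repeat_line":
            return info["length"]
        if kind == "repeat":
            return _CLASS_TEMPLATE_LENGTHS[info["class"]]
        if kind == "gene":
            return 600
        if kind == "ncrna":
            return 100
        return 300  # pseudogene

    order = rng.permutation(len(plans))
    plans = [plans[i] for i in order]
    # a copied miRNA locus must be realised after its template locus
    plans.sort(key=lambda p: p[0] == "mirna_copy")
    total_len = sum(plan_length(k, q) for k, q in plans)
    n_gaps = len(plans) + 1
    min_gap = 60
    slack = genome_length - total_len - min_gap * n_gaps
    if slack < 0:
        raise ValueError(
            f"genome of {genome_length} bp cannot hold {total_len} bp of "
            "planted loci — increase genome_length or reduce counts"
        )
    gaps = min_gap + rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))

    # ---- realise loci ----------------------------------------------------
    pre_mirnas: list[tuple[str, GenomicInterval]] = []
    matures: dict[str, MatureMiRNARecord] = {}
    mature_parents: dict[tuple[str, int], str] = {}
    mature_seqs: dict[str, str] = {}
    features: list[FeatureRecord] = []
    repeat_instances: list[RepeatInstance] = []
    mirna_locus_layout: dict[int, dict] = {}
    occupied: list[tuple[int, int]] = []

    cursor = int(gaps[0])
    for gap_idx, (kind, info) in enumerate(plans):
        ln = plan_length(kind, info)
        start, end = cursor, cursor + ln
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "mirna":
            i = info["idx"]
            m0 = start + 8
            m1 = m0 + info["mature_len"]
            s0 = m1 + 15
            s1 = s0 + info["star_len"]
            pre_id = f"syn-mir-{i}"
            iv = GenomicInterval(chrom, start, end, strand)
            pre_mirnas.append((pre_id, iv))
            mirna_locus_layout[i] = {
                "start": start, "end": end, "strand": strand,
                "m_off": (m0 - start, m1 - start), "s_off": (s0 - start, s1 - start),
            }
            for name, arm, a, b in (
                (f"syn-miR-{i}", "mature", m0, m1),
                (f"syn-miR-{i}*", "star", s0, s1),
            ):
                rec = matures.setdefault(name, MatureMiRNARecord(name=name, arm=arm))
                mature_parents[(name, len(rec.intervals))] = pre_id
                rec.intervals.append(GenomicInterval(chrom, a, b, strand))
                raw = "".join(genome[a:b])
                mature_seqs[name] = raw if strand == "+" else revcomp(raw)
        elif kind == "mirna_copy":
            i = info["idx"]
            lay = mirna_locus_layout[i]
            src = genome[lay["start"] : lay["end"]]
            genome[start:end] = src
            strand = lay["strand"]  # exact copy keeps the template strand
            pre_id = f"syn-mir-{i}-2"
            pre_mirnas.append((pre_id, GenomicInterval(chrom, start, end, strand)))
            for name, off in (
                (f"syn-miR-{i}", lay["m_off"]),
                (f"syn-miR-{i}*", lay["s_off"]),
            ):
                rec = matures[name]
                mature_parents[(name, len(rec.intervals))] = pre_id
                rec.intervals.append(
                    GenomicInterval(chrom, start + off[0], start + off[1], strand)
                )
        elif kind == "repeat_line":
            seg = consensus[l1_name][info["offset"] : info["offset"] + info["length"]]
            if strand == "-":
                seg = revcomp(seg)
            genome[start:end] = list(seg)
            repeat_instances.append(
                RepeatInstance(
                    GenomicInterval(chrom, start, end, strand),
                    "LINE",
                    f"L1_syn_{info['idx']}",
                )
            )
        elif kind == "repeat":
            cls = info["class"]
            seg = templates[cls]
            if strand == "-":
                seg = revcomp(seg)
            genome[start:end] = list(seg)
            repeat_instances.append(
                RepeatInstance(
                    GenomicInterval(chrom, start, end, strand),
                    cls,
                    f"{cls}_{info['idx']}",
                )
            )
        elif kind == "gene":
            iv = GenomicInterval(chrom, start, end, strand)
            name = f"gene{info['idx']}"
            features.append(FeatureRecord(iv, "gene", name))
            for e, (a, b) in enumerate(((start + 50, start + 200), (end - 200, end - 50))):
                features.append(
                    FeatureRecord(
                        GenomicInterval(chrom, a, b, strand), "exon", f"{name}_ex{e}"
                    )
                )
        elif kind == "ncrna":
            features.append(
                FeatureRecord(
                    GenomicInterval(chrom, start, end, strand),
                    "other ncRNA",
                    f"ncRNA{info['idx']}",
                )
            )
        else:  # pseudogene
            features.append(
                FeatureRecord(
                    GenomicInterval(chrom, start, end, strand),
                    "pseudogene",
                    f"pseudo{info['idx']}",
                )
            )
        occupied.append((start, end))
        cursor = end + int(gaps[gap_idx + 1])

    genome_str = "".join(genome)

    # feature-free background windows (margin avoids boundary overlaps)
    margin = 35
    free_windows: list[tuple[str, int, int]] = []
    prev_end = 0
    for a, b in sorted(occupied):
        if a - margin - (prev_end + margin) >= 40:
            free_windows.append((chrom, prev_end + margin, a - margin))
        prev_end = b
    if genome_length - margin - (prev_end + margin) >= 40:
        free_windows.append((chrom, prev_end + margin, genome_length - margin))

    bundle = ReferenceBundle(
        genome={chrom: genome_str},
        pre_mirnas=pre_mirnas,
        matures=matures,
        mature_parents=mature_parents,
        mature_seqs=mature_seqs,
        features=features,
        repeat_instances=repeat_instances,
        consensus=consensus,
        consensus_regions=regions,
        free_windows=free_windows,
    )

    # copy-number bookkeeping must match the realised genome exactly
    for name, rec in matures.items():
        found = _count_occurrences(genome_str, mature_seqs[name])
        if found != rec.copy_count:
            raise ValueError(
                f"copy-number bookkeeping violated for {name}: planted "
                f"{rec.copy_count} copies but the genome contains {found}"
            )
    return bundle


@dataclass
class SimulatedLibrary:
    """One FASTQ library plus its per-read provenance and realised truth."""

    library_id: str
    profile: ProtocolProfile
    reads: list[tuple[str, str]]  # (read id, raw sequence incl. adapter)
    provenance: pd.DataFrame  # read_id, source, chrom, start, end, strand, ...
    realized_counts: pd.Series  # per-species emitted read counts

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def write_fastq(self, path: str | Path) -> None:
        sio.write_fastq(path, self.reads)


def simulate_library(
    reference: ReferenceBundle,
    truth: Mapping[str, int],
    profile: ProtocolProfile,
    seed: int,
    library_id: str = "lib",
    read_length: int = READ_LENGTH,
) -> SimulatedLibrary:
    """Sample one protocol-biased library from a per-species truth table.

    ``truth`` gives the baseline expected read count per mature/star
    species. With ``star_enrichment == 1`` the emitted per-species counts
    equal the truth exactly; otherwise the per-library total is redrawn
    multinomially with star species up-weighted by the enrichment factor.
    Background ("unannotated") reads are drawn uniformly from feature-free
    genomic windows, and repeat-derived (frequently multi-mapping) reads
    from inside annotated repeat instances, both with insert lengths from
    the profile's truncated discrete Gaussian; each read then runs into the
    3' adapter with the profile's read-through probability.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    unknown = sorted(set(truth) - set(reference.matures))
    if unknown:
        raise ValueError(f"truth names unknown species: {unknown}")
    if any(int(c) < 0 for c in truth.values()):
        raise ValueError("truth counts must be non-negative")
    rng = np.random.default_rng(seed)
    chrom = next(iter(reference.genome))
    genome_str = reference.genome[chrom]

    species = sorted(truth)
    base = np.array([int(truth[s]) for s in species], dtype=float)
    n_annotated = int(base.sum())
    if profile.star_enrichment == 1.0:
        realized = base.astype(int)
    else:
        weights = base * np.array(
            [
                profile.star_enrichment if reference.matures[s].arm == "star" else 1.0
                for s in species
            ]
        )
        if weights.sum() == 0:
            realized = np.zeros(len(species), dtype=int)
        else:
            realized = rng.multinomial(n_annotated, weights / weights.sum())

    u, r = profile.unannotated_fraction, profile.repeat_fraction
    denom = 1.0 - u - r
    n_unannotated = int(round(n_annotated * u / denom))
    n_repeat = int(round(n_annotated * r / denom))
    if n_unannotated > 0 and not reference.free_windows:
        raise ValueError("reference has no feature-free windows for background reads")
    if n_repeat > 0 and not reference.repeat_instances:
        raise ValueError("reference has no repeat instances for repeat reads")

    entries: list[tuple[str, str, int, int, str, str]] = []
    for name, count in zip(species, realized):
        rec = reference.matures[name]
        insert = reference.mature_seqs[name]
        iv = rec.intervals[0]
        for _ in range(int(count)):
            entries.append((name, iv.chrom, iv.start, iv.end, iv.strand, insert))

    if n_repeat > 0:
        lengths = sample_insert_lengths(
            rng, n_repeat, profile.modal_length, profile.length_sd, hi=26
        )
        inst_sizes = np.array(
            [inst.interval.length for inst in reference.repeat_instances], dtype=float
        )
        for ln in lengths:
            ln = int(ln)
            capacity = np.maximum(inst_sizes - ln + 1, 0)
            probs = capacity / capacity.sum()
            inst = reference.repeat_instances[
                rng.choice(len(reference.repeat_instances), p=probs)
            ]
            start = int(rng.integers(inst.interval.start, inst.interval.end - ln + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            raw = genome_str[start : start + ln]
            insert = raw if strand == "+" else revcomp(raw)
            entries.append(
                (f"repeat:{inst.repeat_class}", chrom, start, start + ln, strand, insert)
            )

    if n_unannotated > 0:
        lengths = sample_insert_lengths(
            rng, n_unannotated, profile.modal_length, profile.length_sd
        )
        win_sizes = np.array([b - a for _, a, b in reference.free_windows], dtype=float)
        for ln in lengths:
            ln = int(ln)
            capacity = np.maximum(win_sizes - ln + 1, 0)
            probs = capacity / capacity.sum()
            widx = rng.choice(len(reference.free_windows), p=probs)
            _, wa, wb = reference.free_windows[widx]
            start = int(rng.integers(wa, wb - ln + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            raw = genome_str[start : start + ln]
            insert = raw if strand == "+" else revcomp(raw)
            entries.append(("unannotated", chrom, start, start + ln, strand, insert))

    order = rng.permutation(len(entries))
    reads: list[tuple[str, str]] = []
    prov_rows = []
    for out_idx, src_idx in enumerate(order):
        source, ch, a, b, strand, insert = entries[src_idx]
        read_id = f"{library_id}:{out_idx:06d}"
        readthrough = bool(rng.random() < profile.readthrough_prob)
        seq = (insert + profile.adapter)[:read_length] if readthrough else insert
        reads.append((read_id, seq))
        prov_rows.append(
            {
                "read_id": read_id,
                "source": source,
                "chrom": ch,
                "start": a,
                "end": b,
                "strand": strand,
                "insert_length": len(insert),
                "readthrough": readthrough,
            }
        )
    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "read_id", "source", "chrom", "start", "end", "strand",
            "insert_length", "readthrough",
        ],
    )
    realized_counts = pd.Series(0, index=sorted(reference.matures), dtype=int)
    for name, count in zip(species, realized):
        realized_counts[name] = int(count)
    realized_counts.name = library_id
    return SimulatedLibrary(
        library_id=library_id,
        profile=profile,
        reads=reads,
        provenance=provenance,
        realized_counts=realized_counts,
    )


def make_truth(
    reference: ReferenceBundle,
    total_reads: int,
    seed: int,
    effect: Mapping[str, float] | None = None,
    star_fraction: float = 0.15,
    replicate_sigma: float = 0.0,
    replicate_seed: int | None = None,
) -> dict[str, int]:
    """Baseline truth table: lognormal mature abundances, stars at a fixed
    fraction of their mature partner, optionally scaled per species by an
    ``effect`` factor (e.g. a planted cell-type difference).

    With ``replicate_sigma > 0`` a per-species lognormal jitter (driven by
    ``replicate_seed``) is layered on top, so several replicate libraries
    can share one biological baseline (same ``seed``) while differing the
    way biological replicates do.
    """
    rng = np.random.default_rng(seed)
    matures = sorted(n for n, r in reference.matures.items() if r.arm == "mature")
    abundance: dict[str, float] = {}
    for name in matures:
        a = float(rng.lognormal(mean=0.0, sigma=1.0))
        abundance[name] = a
        abundance[name + "*"] = a * star_fraction
    if effect:
        for name, f in effect.items():
            if name in abundance:
                abundance[name] *= f
    if replicate_sigma > 0.0:
        jitter_rng = np.random.default_rng(
            replicate_seed if replicate_seed is not None else seed + 1
        )
        for name in sorted(abundance):
            abundance[name] *= float(jitter_rng.lognormal(0.0, replicate_sigma))
    total = sum(abundance.values())
    truth = {
        name: int(round(total_reads * a / total)) for name, a in abundance.items()
    }
    return truth


def simulate_consensus_reads(
    reference: ReferenceBundle,
    consensus_name: str,
    seed: int,
    n_promoter_sense: int = 100,
    n_promoter_antisense: int = 100,
    n_orf_sense: int = 200,
    modal_length: int = 22,
    length_sd: float = 1.5,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Plant reads directly on a repeat consensus (L1-style experiment).

    Sense and antisense reads are drawn from the promoter sub-interval and
    sense-only reads from the ORF region; returns (reads, truth table).
    """
    rng = np.random.default_rng(seed)
    seq = reference.consensus[consensus_name]
    regions = reference.consensus_regions[consensus_name]
    specs = [
        ("promoter", "+", n_promoter_sense),
        ("promoter", "-", n_promoter_antisense),
        ("orf", "+", n_orf_sense),
    ]
    reads: list[tuple[str, str]] = []
    rows = []
    idx = 0
    for region, strand, n in specs:
        a, b = regions[region]
        lengths = sample_insert_lengths(rng, n, modal_length, length_sd, lo=19, hi=26)
        for ln in lengths:
            ln = int(ln)
            start = int(rng.integers(a, b - ln + 1))
            insert = seq[start : start + ln]
            if strand == "-":
                insert = revcomp(insert)
            read_id = f"{consensus_name}:{idx:05d}"
            idx += 1
            reads.append((read_id, insert))
            rows.append(
                {
                    "read_id": read_id,
                    "region": region,
                    "strand": strand,
                    "start": start,
                    "end": start + ln,
                }
            )
    return reads, pd.DataFrame(rows)
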
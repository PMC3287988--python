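"""Format readers and writers.

All conversions between the internal 0-based half-open convention and the
on-disk conventions (GFF3/SAM 1-based inclusive, BED 0-based half-open)
live here and nowhere else.
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignmentRecord, FeatureRecord, GenomicInterval, MatureMiRNARecord

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # wraps at 60 columns


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) pairs; qualities are ignored downstream."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write 4-line FASTQ records with constant quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# miRNA GFF3 (miRBase-like hierarchy: miRNA_primary_transcript parent,
# miRNA children carrying Name and arm=mature|star attributes)


def write_mirna_gff3(
    path: str | Path,
    pre_mirnas: list[tuple[str, GenomicInterval]],
    matures: dict[str, MatureMiRNARecord],
    mature_parents: dict[tuple[str, int], str],
) -> None:
    """Write the pre-miRNA/mature hierarchy.

    ``mature_parents`` maps (species name, copy index) to the parent
    pre-miRNA id so multi-copy species resolve to distinct parents.
    """
    lines = ["##gff-version 3"]
    for pre_id, iv in pre_mirnas:
        lines.append(
            f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\tID={pre_id};Name={pre_id}"
        )
    for name, rec in sorted(matures.items()):
        for idx, iv in enumerate(rec.intervals):
            parent = mature_parents[(name, idx)]
            uid = f"{name}_copy{idx}" if rec.copy_count > 1 else name
            lines.append(
                f"{iv.chrom}\t.\tmiRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={uid};Name={name};arm={rec.arm};Parent={parent}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mirna_gff3(
    path: str | Path,
) -> tuple[list[tuple[str, GenomicInterval]], dict[str, MatureMiRNARecord]]:
    """Read pre-miRNA intervals and mature/star species (grouped by Name).

    A species' copy count is the number of miRNA features sharing its Name.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    pre_mirnas: list[tuple[str, GenomicInterval]] = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        pre_mirnas.append((feat.attributes["ID"][0], iv))
    matures: dict[str, MatureMiRNARecord] = {}
    for feat in db.features_of_type("miRNA"):
        name = feat.attributes["Name"][0]
        arm = feat.attributes.get("arm", ["mature"])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        rec = matures.setdefault(name, MatureMiRNARecord(name=name, arm=arm))
        rec.intervals.append(iv)
    for name, rec in matures.items():
        if rec.copy_count == 0:
            raise ValueError(f"miRNA species {name} has zero genomic copies")
    return pre_mirnas, matures


# ---------------------------------------------------------------------------
# BED6

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, names=_BED_COLS, comment="#")
    return df


def write_bed6(path: str | Path, rows: Iterable[tuple[GenomicInterval, str]]) -> None:
    """Write (interval, name) pairs as BED6 with score 0."""
    with open(path, "w") as fh:
        for iv, name in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def features_from_bed(df: pd.DataFrame, class_from_name: bool = True) -> list[FeatureRecord]:
    """Build FeatureRecords from a BED6 frame.

    The feature class is taken from the BED name column as the prefix before
    the first '|' (e.g. ``exon|geneA_ex1``); the remainder is the name.
    """
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        if class_from_name and "|" in row.name:
            cls, name = row.name.split("|", 1)
        else:
            cls, name = row.name, row.name
        out.append(FeatureRecord(interval=iv, feature_class=cls, name=name))
    return out


# ---------------------------------------------------------------------------
# SAM import/export (pysam)


def write_sam(
    path: str | Path,
    records: Iterable[AlignmentRecord],
    reference_lengths: dict[str, int],
    sequences: dict[str, str] | None = None,
) -> None:
    """Write alignment records to a SAM file with a minimal @SQ header.

    Multi-hit reads are emitted as one record per placement; ``NH`` carries
    the total hit count and ``NM`` the mismatch count.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(reference_lengths)}
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.interval.chrom]
            a.reference_start = rec.interval.start
            a.cigarstring = f"{rec.read_length}M"
            a.flag = 16 if rec.interval.strand == "-" else 0
            a.mapping_quality = 255
            if sequences and rec.read_id in sequences:
                a.query_sequence = sequences[rec.read_id]
            a.set_tag("NH", rec.total_hits)
            a.set_tag("NM", rec.mismatches)
            out.write(a)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    """Import mapped records from SAM/BAM; returns (records, skipped unmapped).

    Total hit counts are taken from NH when present, otherwise derived by
    counting records per read id.
    """
    raw: list[tuple[str, GenomicInterval, int, int | None]] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                skipped += 1
                continue
            iv = GenomicInterval(
                a.reference_name,
                a.reference_start,
                a.reference_end,
                "-" if a.is_reverse else "+",
            )
            nm = a.get_tag("NM") if a.has_tag("NM") else 0
            nh = a.get_tag("NH") if a.has_tag("NH") else None
            raw.append((a.query_name, iv, nm, nh))
    per_read = collections.Counter(r[0] for r in raw)
    records = []
    for read_id, iv, nm, nh in raw:
        records.append(
            AlignmentRecord(
                read_id=read_id,
                interval=iv,
                mismatches=int(nm),
                total_hits=int(nh) if nh is not None else per_read[read_id],
                read_length=iv.length,
            )
        )
    return records, skipped


def alignments_from_bed(path: str | Path) -> list[AlignmentRecord]:
    """Import placements from a BED6 file (name column = read id)."""
    df = read_bed6(path)
    per_read = df["name"].value_counts()
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        out.append(
            AlignmentRecord(
                read_id=row.name,
                interval=iv,
                mismatches=0,
                total_hits=int(per_read[row.name]),
                read_length=iv.length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV matrices


def write_matrix(path: str | Path, df: pd.DataFrame, index_label: str = "feature") -> None:
    df.to_csv(str(path), sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=0)
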
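"""Exhaustive best-stratum short-read placement.

The reference aligner scans every genomic offset on both strands and
reports ALL placements achieving the read's minimal Hamming distance
(its "best stratum"), provided that distance does not exceed the mismatch
budget. Ungapped matching mirrors the behaviour of the short-read aligners
this pipeline is designed around; desk-scale genomes make the exhaustive
scan cheap and trivially auditable. Real-scale alignments enter through
SAM/BED import in :mod:`srnaproto.io`.
"""

from __future__ import annotations

import collections
from typing import Iterable, Sequence

import numpy as np

from .core import AlignmentRecord, GenomicInterval, encode_seq, revcomp

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MAX_HITS = 5000
MIN_READ_LENGTH = 15

_VALID = set("ACGTN")


class GenomeIndex:
    """Byte-encoded genome ready for vectorised Hamming scans."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.encoded = {c: encode_seq(s) for c, s in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _scan(chrom_arr: np.ndarray, read_arr: np.ndarray, max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts of the read against every offset of one sequence.

    Returns (offsets, mismatch counts) for offsets with <= max_mm mismatches.
    N (code 4) on either side always counts as a mismatch.
    """
    g, n = len(chrom_arr), len(read_arr)
    if g < n:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.int32)
    mism = np.zeros(g - n + 1, dtype=np.int32)
    for i, base in enumerate(read_arr):
        window = chrom_arr[i : g - n + 1 + i]
        if base == 4:
            mism += 1
        else:
            mism += (window != base) | (window == 4)
    keep = np.flatnonzero(mism <= max_mm)
    return keep, mism[keep]


def find_placements(
    sequence: str, genome: GenomeIndex, max_mismatches: int = DEFAULT_MAX_MISMATCHES
) -> list[tuple[GenomicInterval, int]]:
    """All best-stratum placements of one sequence, both strands.

    Returns (interval, mismatches) pairs; empty if the minimal distance
    exceeds ``max_mismatches``. A reverse-strand placement is the match of
    the read's reverse complement on the forward genome.
    """
    seq = sequence.upper()
    if set(seq) - _VALID:
        raise ValueError(f"read contains non-ACGTN symbols: {seq}")
    if len(seq) < MIN_READ_LENGTH:
        raise ValueError(f"read shorter than {MIN_READ_LENGTH} nt")
    fwd = encode_seq(seq)
    rev = encode_seq(revcomp(seq))
    hits: list[tuple[GenomicInterval, int]] = []
    for chrom, arr in genome.encoded.items():
        for strand, read_arr in (("+", fwd), ("-", rev)):
            offs, mms = _scan(arr, read_arr, max_mismatches)
            for off, mm in zip(offs, mms):
                iv = GenomicInterval(chrom, int(off), int(off) + len(seq), strand)
                hits.append((iv, int(mm)))
    if not hits:
        return []
    best = min(mm for _, mm in hits)
    return sorted(
        ((iv, mm) for iv, mm in hits if mm == best),
        key=lambda h: (h[0].chrom, h[0].start, h[0].strand),
    )


def align_read(
    read_id: str,
    sequence: str,
    genome: GenomeIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[AlignmentRecord]:
    placements = find_placements(sequence, genome, max_mismatches)
    total = len(placements)
    return [
        AlignmentRecord(
            read_id=read_id,
            interval=iv,
            mismatches=mm,
            total_hits=total,
            read_length=len(sequence),
        )
        for iv, mm in placements
    ]


def align_reads(
    reads: Iterable[tuple[str, str]],
    genome: GenomeIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_length: int = MIN_READ_LENGTH,
    cache: dict | None = None,
) -> tuple[list[AlignmentRecord], int]:
    """Align a library; identical sequences are scanned once.

    Reads shorter than ``min_length`` are skipped and counted as unaligned.
    Returns (records, number of unaligned reads). ``cache`` may be shared
    across libraries mapped to the same genome.
    """
    if cache is None:
        cache = {}
    records: list[AlignmentRecord] = []
    unaligned = 0
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < min_length:
            unaligned += 1
            continue
        if seq not in cache:
            cache[seq] = find_placements(seq, genome, max_mismatches)
        placements = cache[seq]
        if not placements:
            unaligned += 1
            continue
        total = len(placements)
        for iv, mm in placements:
            records.append(AlignmentRecord(read_id, iv, mm, total, len(seq)))
    return records, unaligned


def cap_hits(
    records: Iterable[AlignmentRecord], max_hits: int = DEFAULT_MAX_HITS
) -> list[AlignmentRecord]:
    """Drop every record of reads with more than ``max_hits`` placements.

    The bound is inclusive: a read with exactly ``max_hits`` placements is
    retained.
    """
    return [r for r in records if r.total_hits <= max_hits]


def group_by_read(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    grouped: dict[str, list[AlignmentRecord]] = collections.defaultdict(list)
    for rec in records:
        grouped[rec.read_id].append(rec)
    return dict(grouped)
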
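"""Feature-category assignment and mature miRNA / miR* counting.

Category assignment follows the 70%-overlap rule with a fixed priority
order (microRNA > other ncRNA > pseudogene > exon > gene > LINE > other
repeat): among the features covering at least 70% of the read's aligned
length, the highest-priority class wins; a read covering no feature at that
level is "unannotated". Pre-miRNA hairpin intervals serve as the microRNA
category features.

miRNA counting is positional and copy-number aware: a read of 19-26 nt
increments a mature (or star) species only if it sits within the position
tolerance of an annotated copy on the same strand, and has no more genomic
hits than the species has genomic copies. That second rule keeps
multi-mapping reads from inflating single-copy species.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .core import (
    CATEGORY_PRIORITY,
    AlignmentRecord,
    FeatureRecord,
    MatureMiRNARecord,
)

MIRNA_LENGTH_RANGE = (19, 26)
POSITION_TOLERANCE = 2
MIN_OVERLAP_FRACTION = 0.7

_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


class FeatureIndex:
    """Interval-queryable index of FeatureRecords, per chromosome."""

    def __init__(self, features: Iterable[FeatureRecord]):
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        for feat in features:
            iv = feat.interval
            self._trees[iv.chrom].addi(iv.start, iv.end, feat)

    def overlapping(self, chrom: str, start: int, end: int) -> list[FeatureRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


def assign_category(
    alignment: AlignmentRecord,
    features: FeatureIndex,
    min_overlap_fraction: float = MIN_OVERLAP_FRACTION,
) -> str:
    """Category of one placement, or "unannotated".

    Overlap is measured read-relative — (overlapping bases) / (read length)
    — and strand-agnostic.
    """
    iv = alignment.interval
    best: str | None = None
    for feat in features.overlapping(iv.chrom, iv.start, iv.end):
        frac = iv.overlap(feat.interval) / alignment.read_length
        if frac >= min_overlap_fraction:
            if best is None or _RANK[feat.feature_class] < _RANK[best]:
                best = feat.feature_class
    return best if best is not None else "unannotated"


@dataclass
class CategoryTally:
    """Per-category read counts for one library; categories + unannotated
    sum to the total number of aligned reads."""

    counts: dict[str, int]
    total_aligned: int

    def as_series(self) -> pd.Series:
        order = list(CATEGORY_PRIORITY) + ["unannotated"]
        return pd.Series({c: self.counts.get(c, 0) for c in order}, name="reads")


def tally_categories(
    alignments: Iterable[AlignmentRecord],
    features: FeatureIndex,
    min_overlap_fraction: float = MIN_OVERLAP_FRACTION,
) -> CategoryTally:
    """One category per aligned READ: the highest-priority category over all
    of its placements (multi-mapped reads are not double-counted)."""
    best_per_read: dict[str, str | None] = {}
    for rec in alignments:
        cat = assign_category(rec, features, min_overlap_fraction)
        prev = best_per_read.get(rec.read_id)
        if cat != "unannotated" and (
            prev is None or prev == "unannotated" or _RANK[cat] < _RANK[prev]
        ):
            best_per_read[rec.read_id] = cat
        elif prev is None:
            best_per_read[rec.read_id] = cat
    counts: dict[str, int] = collections.Counter(best_per_read.values())
    return CategoryTally(counts=dict(counts), total_aligned=len(best_per_read))


def _within_tolerance(
    read_iv, copy_iv, tolerance: int, mode: str
) -> bool:
    if read_iv.chrom != copy_iv.chrom or read_iv.strand != copy_iv.strand:
        return False
    if mode == "both":
        return (
            abs(read_iv.start - copy_iv.start) <= tolerance
            and abs(read_iv.end - copy_iv.end) <= tolerance
        )
    if mode == "five_prime":
        if read_iv.strand == "+":
            return abs(read_iv.start - copy_iv.start) <= tolerance
        return abs(read_iv.end - copy_iv.end) <= tolerance
    raise ValueError(f"unknown tolerance mode {mode!r}")


def count_mirnas(
    alignments: Iterable[AlignmentRecord],
    mirna_records: Mapping[str, MatureMiRNARecord],
    length_range: tuple[int, int] = MIRNA_LENGTH_RANGE,
    position_tolerance: int = POSITION_TOLERANCE,
    tolerance_mode: str = "both",
) -> pd.Series:
    """Counts per mature/star species for one library.

    A read increments a species iff (a) its trimmed length is within
    ``length_range``; (b) some placement lies within ``position_tolerance``
    bp of an annotated copy, same strand; (c) the read's total genomic hits
    do not exceed the species' genomic copy number. A read satisfying the
    predicate for several species increments each; it never increments one
    species more than once.
    """
    for name, rec in mirna_records.items():
        if rec.copy_count == 0:
            raise ValueError(f"species {name} has zero genomic copies")
    # index copies by chromosome for fast lookup
    trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    for name, rec in mirna_records.items():
        for copy_iv in rec.intervals:
            trees[copy_iv.chrom].addi(
                max(0, copy_iv.start - position_tolerance),
                copy_iv.end + position_tolerance,
                (name, copy_iv),
            )
    lo, hi = length_range
    hits_per_read: dict[str, set[str]] = collections.defaultdict(set)
    for rec in alignments:
        if not (lo <= rec.read_length <= hi):
            continue
        tree = trees.get(rec.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(rec.interval.start, rec.interval.end):
            name, copy_iv = hit.data
            if rec.total_hits > mirna_records[name].copy_count:
                continue
            if _within_tolerance(rec.interval, copy_iv, position_tolerance, tolerance_mode):
                hits_per_read[rec.read_id].add(name)
    counts = pd.Series(0, index=sorted(mirna_records), dtype=int, name="count")
    for species_set in hits_per_read.values():
        for name in species_set:
            counts[name] += 1
    return counts


def detection_summary(count_matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """Distribution of per-species detection breadth.

    Returns a histogram over "number of libraries with >= 1 read"
    (0..n_libraries) and the fraction of species detected in ALL libraries
    among species detected anywhere.
    """
    n_libs = count_matrix.shape[1]
    detected = (count_matrix > 0).sum(axis=1)
    hist = detected.value_counts().reindex(range(0, n_libs + 1), fill_value=0)
    hist.index.name = "n_libraries"
    anywhere = detected > 0
    if anywhere.sum() == 0:
        return hist, float("nan")
    frac_all = float((detected == n_libs).sum() / anywhere.sum())
    return hist, frac_all
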
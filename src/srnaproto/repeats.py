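"""Repeat-derived small-RNA profiling.

Reads that (after pre-miRNA exclusion, the 19-26 nt size filter and the
5000-hit cap) fall inside annotated repeat instances are tallied per repeat
class; class counts are normalised by the number of genomic instances of
the class to give a mean coverage per instance. A separate consensus-level
analysis aligns reads directly onto repeat consensus sequences (e.g. an
L1-like element) and accumulates strand-resolved per-position depth, the
view in which LINE-1 promoter-region sense/antisense small RNAs stand out.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import DEFAULT_MAX_HITS, GenomeIndex, align_reads
from .core import AlignmentRecord, GenomicInterval

REPEAT_LENGTH_RANGE = (19, 26)
CLASS_TOLERANCE = 2
#: Dominant housekeeping-RNA classes excluded in the "highlight" profile view.
MAJOR_RNA_CLASSES = frozenset({"RNA", "rRNA", "tRNA"})


@dataclass(frozen=True)
class RepeatInstance:
    interval: GenomicInterval
    repeat_class: str
    name: str = ""


def filter_repeat_reads(
    alignments: Iterable[AlignmentRecord],
    pre_mirna_intervals: Iterable[GenomicInterval],
    length_range: tuple[int, int] = REPEAT_LENGTH_RANGE,
    max_hits: int = DEFAULT_MAX_HITS,
) -> list[AlignmentRecord]:
    """Keep alignments of reads eligible for repeat profiling.

    A read is removed entirely if ANY of its placements overlaps a
    pre-miRNA, if its length is outside ``length_range``, or if it has more
    than ``max_hits`` placements (inclusive bound).
    """
    trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    for iv in pre_mirna_intervals:
        trees[iv.chrom].addi(iv.start, iv.end)
    records = list(alignments)
    excluded_reads = set()
    lo, hi = length_range
    for rec in records:
        if not (lo <= rec.read_length <= hi) or rec.total_hits > max_hits:
            excluded_reads.add(rec.read_id)
            continue
        tree = trees.get(rec.interval.chrom)
        if tree is not None and tree.overlap(rec.interval.start, rec.interval.end):
            excluded_reads.add(rec.read_id)
    return [r for r in records if r.read_id not in excluded_reads]


def assign_repeat_class(
    alignment: AlignmentRecord,
    repeat_index: "RepeatIndex",
    tolerance: int = CLASS_TOLERANCE,
) -> set[str]:
    """Repeat classes whose instances contain the placement (with slack).

    Containment-with-slack: the read interval must lie inside an instance
    interval expanded by ``tolerance`` bp on each side. A read may collect
    several class labels.
    """
    return repeat_index.containing_classes(alignment.interval, tolerance)


class RepeatIndex:
    def __init__(self, instances: Iterable[RepeatInstance]):
        self.instances = list(instances)
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        for inst in self.instances:
            iv = inst.interval
            self._trees[iv.chrom].addi(iv.start, iv.end, inst)

    def containing_classes(self, iv: GenomicInterval, tolerance: int) -> set[str]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return set()
        classes = set()
        for hit in tree.overlap(iv.start, iv.end):
            inst = hit.data
            if (
                iv.start >= inst.interval.start - tolerance
                and iv.end <= inst.interval.end + tolerance
            ):
                classes.add(inst.repeat_class)
        return classes

    def instance_counts(self) -> pd.Series:
        counts = collections.Counter(inst.repeat_class for inst in self.instances)
        return pd.Series(counts, name="instances").sort_index()


def assign_repeat_reads(
    alignments: Iterable[AlignmentRecord],
    repeat_index: RepeatIndex,
    tolerance: int = CLASS_TOLERANCE,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-read class label sets and per-read length, over all placements.

    Multi-mapped reads contribute once per distinct class, never more.
    """
    classes_per_read: dict[str, set[str]] = collections.defaultdict(set)
    length_per_read: dict[str, int] = {}
    for rec in alignments:
        labels = assign_repeat_class(rec, repeat_index, tolerance)
        if labels:
            classes_per_read[rec.read_id] |= labels
            length_per_read[rec.read_id] = rec.read_length
    return dict(classes_per_read), length_per_read


@dataclass
class RepeatClassProfile:
    """Per-class read counts, instance-normalised coverage and proportions,
    in a full view and with the dominant RNA classes excluded."""

    full: pd.DataFrame  # columns: reads, instances, mean_coverage, proportion
    highlighted: pd.DataFrame  # same, excluding MAJOR_RNA_CLASSES
    length_histograms: pd.DataFrame  # classes x lengths 19..26


def class_profile(
    classes_per_read: Mapping[str, set[str]],
    length_per_read: Mapping[str, int],
    instance_counts: pd.Series,
    exclude_classes: frozenset = MAJOR_RNA_CLASSES,
    length_range: tuple[int, int] = REPEAT_LENGTH_RANGE,
) -> RepeatClassProfile:
    read_counts: collections.Counter = collections.Counter()
    lo, hi = length_range
    hist = collections.defaultdict(lambda: {n: 0 for n in range(lo, hi + 1)})
    for read_id, labels in classes_per_read.items():
        for cls in labels:
            read_counts[cls] += 1
            hist[cls][length_per_read[read_id]] += 1
    for cls in read_counts:
        if cls not in instance_counts.index or instance_counts[cls] <= 0:
            raise ValueError(
                f"class {cls!r} has assigned reads but no recorded genomic instances"
            )

    def build(classes: list[str]) -> pd.DataFrame:
        reads = pd.Series({c: read_counts.get(c, 0) for c in classes}, dtype=float)
        inst = instance_counts.reindex(classes).astype(float)
        cov = reads / inst
        total = reads.sum()
        prop = reads / total if total > 0 else reads * np.nan
        return pd.DataFrame(
            {"reads": reads.astype(int), "instances": inst.astype(int),
             "mean_coverage": cov, "proportion": prop}
        )

    all_classes = sorted(instance_counts.index)
    full = build(all_classes)
    highlighted = build([c for c in all_classes if c not in exclude_classes])
    length_histograms = pd.DataFrame(
        {cls: pd.Series(hist[cls]) for cls in all_classes}
    ).T.fillna(0).astype(int)
    return RepeatClassProfile(full=full, highlighted=highlighted,
                              length_histograms=length_histograms)


@dataclass
class ConsensusCoverage:
    """Strand-resolved per-position depth over one consensus sequence."""

    name: str
    sense: np.ndarray
    antisense: np.ndarray
    length_histogram: pd.Series = field(default_factory=pd.Series)
    n_aligned_reads: int = 0

    @property
    def total_depth(self) -> int:
        return int(self.sense.sum() + self.antisense.sum())


def consensus_coverage(
    reads: Iterable[tuple[str, str]],
    consensus_name: str,
    consensus_seq: str,
    max_mismatches: int = 2,
) -> ConsensusCoverage:
    """Align reads onto a repeat consensus and accumulate stranded depth.

    Uses the same exhaustive best-stratum engine as genomic alignment;
    every best-stratum placement contributes depth (coverage semantics),
    so total depth equals the sum of aligned placement lengths exactly.
    """
    if not consensus_seq:
        raise ValueError("empty consensus sequence")
    genome = GenomeIndex({consensus_name: consensus_seq})
    records, _ = align_reads(list(reads), genome, max_mismatches)
    n = len(consensus_seq)
    sense = np.zeros(n, dtype=np.int64)
    antisense = np.zeros(n, dtype=np.int64)
    lengths: collections.Counter = collections.Counter()
    aligned_reads = set()
    for rec in records:
        target = sense if rec.interval.strand == "+" else antisense
        target[rec.interval.start : rec.interval.end] += 1
        lengths[rec.read_length] += 1
        aligned_reads.add(rec.read_id)
    hist = pd.Series(lengths, dtype=int).sort_index()
    return ConsensusCoverage(
        name=consensus_name,
        sense=sense,
        antisense=antisense,
        length_histogram=hist,
        n_aligned_reads=len(aligned_reads),
    )
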
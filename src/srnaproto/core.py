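"""Shared coordinate and sequence primitives.

Every module of the pipeline speaks 0-based half-open genomic coordinates
internally; conversion to the 1-based conventions of GFF3 and SAM happens
only inside the format readers/writers in :mod:`srnaproto.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Feature categories in annotation priority order (highest first).
CATEGORY_PRIORITY: tuple[str, ...] = (
    "microRNA",
    "other ncRNA",
    "pseudogene",
    "exon",
    "gene",
    "LINE",
    "other repeat",
)

#: Repeat classes recognised by the repeat profiler.
REPEAT_CLASSES: tuple[str, ...] = (
    "RNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "scRNA",
    "srpRNA",
    "LINE",
    "other",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Base -> integer code used by the exhaustive aligner. N maps to 4 and
#: never matches anything, including another N.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    try:
        return np.fromiter(
            (_BASE_CODE[b] for b in seq.upper()), dtype=np.uint8, count=len(seq)
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"non-ACGTN symbol in sequence: {exc}") from exc


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open.

    ``start`` is inclusive, ``end`` exclusive; ``length == end - start``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (strand-agnostic; 0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of a read on the genome.

    ``total_hits`` is the number of best-stratum placements this read has
    genome-wide; it is identical across all records of one read.
    """

    read_id: str
    interval: GenomicInterval
    mismatches: int
    total_hits: int
    read_length: int

    def __post_init__(self) -> None:
        if self.interval.length != self.read_length:
            raise ValueError(
                f"interval length {self.interval.length} != read length "
                f"{self.read_length} for {self.read_id}"
            )
        if self.total_hits < 1:
            raise ValueError("total_hits must be >= 1")


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated genomic feature used for category assignment."""

    interval: GenomicInterval
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.feature_class not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.interval.length == 0:
            raise ValueError("feature interval must be non-empty")


@dataclass
class MatureMiRNARecord:
    """A mature or star miRNA species with one interval per genomic copy."""

    name: str
    arm: str  # "mature" | "star"
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arm not in ("mature", "star"):
            raise ValueError(f"arm must be 'mature' or 'star', got {self.arm!r}")

    @property
    def copy_count(self) -> int:
        return len(self.intervals)
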
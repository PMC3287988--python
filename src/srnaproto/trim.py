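"""3'-adapter removal by maximal suffix/prefix overlap.

Small-RNA reads are usually longer than the sequenced insert, so the read
runs into the ligated 3' adapter. Trimming finds the longest suffix of the
read that matches a prefix of the adapter (within a mismatch budget) and
cuts immediately in front of the first adapter base. Reads without a
detectable adapter are retained untrimmed and flagged, so downstream length
filters decide their fate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCHES = 0

#: Insert size range selected for sequencing; trimmed lengths outside it are
#: flagged out-of-range in the histogram report.
LENGTH_RANGE = (19, 30)


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sequence: str  # trimmed sequence (prefix of the original read)
    original_length: int
    overlap_length: int  # adapter bases removed; 0 if no adapter found
    trimmed: bool

    def __post_init__(self) -> None:
        if self.trimmed and len(self.sequence) + self.overlap_length != self.original_length:
            raise ValueError("trimmed length + overlap must equal original length")


def find_adapter_cut(
    read_sequence: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> int | None:
    """0-based position of the first adapter base in the read, or None.

    Scans every suffix of the read against the same-length prefix of the
    adapter and returns the cut giving the LONGEST qualifying overlap
    (at most ``max_mismatches`` mismatching positions; N never matches).
    Overlaps longer than the adapter itself are not suffix/prefix overlaps
    and are not considered.
    """
    if not read_sequence or not adapter:
        raise ValueError("read and adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = read_sequence.upper()
    ad = adapter.upper()
    n = len(read)
    # smallest cut = longest overlap; overlap cannot exceed adapter length
    for cut in range(max(0, n - len(ad)), n - min_overlap + 1):
        overlap = n - cut
        mm = 0
        for r, a in zip(read[cut:], ad[:overlap]):
            if r != a or r == "N" or a == "N":
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return cut
    return None


def trim_read(
    read_id: str,
    sequence: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    _cache: dict | None = None,
) -> TrimmedRead:
    if _cache is not None and sequence in _cache:
        cut = _cache[sequence]
    else:
        cut = find_adapter_cut(sequence, adapter, min_overlap, max_mismatches)
        if _cache is not None:
            _cache[sequence] = cut
    if cut is None:
        return TrimmedRead(read_id, sequence, len(sequence), 0, False)
    return TrimmedRead(read_id, sequence[:cut], len(sequence), len(sequence) - cut, True)


def trim_library(
    reads: Iterable[tuple[str, str]],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[TrimmedRead], pd.Series]:
    """Trim every read and tabulate trimmed lengths.

    Returns the trimmed reads (all reads are retained, trimmed or not) and a
    length histogram over 19-30 nt plus an ``out_of_range`` bin; the
    histogram sums to the number of reads.
    """
    cache: dict[str, int | None] = {}
    out: list[TrimmedRead] = []
    lo, hi = LENGTH_RANGE
    hist = {length: 0 for length in range(lo, hi + 1)}
    out_of_range = 0
    for read_id, seq in reads:
        tr = trim_read(read_id, seq, adapter, min_overlap, max_mismatches, _cache=cache)
        out.append(tr)
        n = len(tr.sequence)
        if lo <= n <= hi:
            hist[n] += 1
        else:
            out_of_range += 1
    series = pd.Series(hist, name="reads")
    series.loc["out_of_range"] = out_of_range
    return out, series


def trimmed_sequences(trimmed: Iterable[TrimmedRead]) -> Iterator[tuple[str, str]]:
    for tr in trimmed:
        yield tr.read_id, tr.sequence
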
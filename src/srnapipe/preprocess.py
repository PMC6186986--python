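"""3' adapter trimming and read-length filtering.

Small-RNA libraries sequence through the insert into the 3' ligation adapter,
so the adapter (or a prefix of it, for longer inserts) appears at the read's
3' end and must be removed before alignment. Defaults follow the common
single-end TruSeq small-RNA chemistry: adapter TGGAATTCTCGGGTGCCAAGG, up to a
10% mismatch rate over the matched adapter bases, and a minimum 3-base
overlap to limit chance matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .sequence_io import SmallRead

#: TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ERROR_RATE = 0.1
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MIN_LEN = 16
DEFAULT_MAX_LEN = 36


@dataclass
class TrimResult:
    read: SmallRead
    adapter_found: bool
    trimmed_bases: int


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance between equal-length strings, early-exiting past limit."""
    count = 0
    for x, y in zip(a, b):
        if x != y:
            count += 1
            if count > limit:
                return count
    return count


def trim_adapter(
    read: SmallRead,
    adapter: str = DEFAULT_ADAPTER,
    max_error_rate: float = DEFAULT_ERROR_RATE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> TrimResult:
    """Remove the best-supported 3' adapter occurrence from a read.

    A candidate is a position ``p`` and adapter-prefix length ``L`` such that
    ``adapter[:L]`` aligns at read positions ``[p, p+L)`` and either reaches
    the read's 3' end (a partial adapter on a long insert) or is the full
    adapter placed internally (read-through past the adapter), with
    ``L >= min_overlap`` and at most ``floor(max_error_rate * L)`` mismatches.
    Among valid candidates the one with the fewest mismatches wins; ties go to
    the smallest ``p``, i.e. the most aggressive trim, so partially degraded
    adapter dimers are removed rather than kept. The read (and its qualities)
    are truncated to ``[0, p)``; a read that is pure adapter comes back empty.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not (0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    seq = read.sequence
    n, alen = len(seq), len(adapter)
    best: tuple[int, int] | None = None  # (mismatches, p)
    for p in range(n):
        # Candidate 1: adapter prefix reaching the 3' end.
        L = n - p
        if min_overlap <= L <= alen:
            limit = math.floor(max_error_rate * L)
            mm = _mismatches(adapter[:L], seq[p:], limit)
            if mm <= limit and (best is None or (mm, p) < best):
                best = (mm, p)
        # Candidate 2: full adapter internal to the read.
        if alen >= min_overlap and p + alen < n:
            limit = math.floor(max_error_rate * alen)
            mm = _mismatches(adapter, seq[p : p + alen], limit)
            if mm <= limit and (best is None or (mm, p) < best):
                best = (mm, p)

    if best is None:
        return TrimResult(read=read, adapter_found=False, trimmed_bases=0)
    p = best[1]
    trimmed = SmallRead(read.read_id, seq[:p] if p else "", read.qualities[:p])
    return TrimResult(read=trimmed, adapter_found=True, trimmed_bases=n - p)


@dataclass
class LengthFilterResult:
    """Reads surviving the size selection, plus the discard tallies."""

    kept: list[SmallRead] = field(default_factory=list)
    below: int = 0
    above: int = 0


def filter_by_length(
    reads: Iterable[SmallRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> LengthFilterResult:
    """Keep reads whose length is within ``[min_len, max_len]`` inclusive.

    The 16-36 nt default spans the mature small-RNA size range (miRNA/siRNA
    around 21-23 nt, piRNA up to ~32 nt) while excluding adapter dimers and
    undigested fragments.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    result = LengthFilterResult()
    for read in reads:
        n = len(read.sequence)
        if n < min_len:
            result.below += 1
        elif n > max_len:
            result.above += 1
        else:
            result.kept.append(read)
    return result
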
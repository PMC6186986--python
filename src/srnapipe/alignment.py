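"""rRNA contaminant filtering and exhaustive ungapped genome alignment.

Two mapping regimes mirror typical small-RNA practice:

* contaminant filtering against an rRNA reference with up to two mismatches,
  best-hit-only — only the mapped/unmapped decision matters;
* genome alignment with zero mismatches, reporting *all* placements, and
  suppressing reads that map to more than ``max_loci`` (default 100) loci.
  The retained placement count ``n`` defines the 1/n multimapper weight used
  downstream.

The built-in aligner is exhaustive by contract: its results equal a naive
Hamming-distance scan of every position on both strands. An 'N' in a read
mismatches every reference base (and reference 'N' mismatches everything,
including read 'N'), so N-containing reads cannot map at zero mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sequence_io import AlignmentRecord, SmallRead, read_fasta, reverse_complement

DEFAULT_MAX_LOCI = 100
DEFAULT_RRNA_MISMATCHES = 2

# Reference N encodes to 4, read N to 5: N never matches anything.
_REF_ENCODE = np.full(256, 4, dtype=np.uint8)
_READ_ENCODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _REF_ENCODE[_b] = _i
    _READ_ENCODE[_b] = _i


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ReadAlignmentSet:
    """All retained placements of one read; ``n`` drives the 1/n weight."""

    read_id: str
    read: SmallRead
    alignments: list[AlignmentRecord]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError(f"alignment set for {self.read_id!r} is empty")
        if any(a.read_id != self.read_id for a in self.alignments):
            raise ValueError(f"alignment set for {self.read_id!r} mixes read ids")

    @property
    def n(self) -> int:
        return len(self.alignments)

    @property
    def weight(self) -> float:
        return 1.0 / self.n


class ReferenceIndex:
    """Reference sequences supporting exhaustive two-strand mismatch queries.

    Holds each chromosome as an encoded byte array and scans every window of
    read length on both strands; results are memoised per (sequence,
    parameters) since small-RNA libraries are dominated by repeated
    sequences. Equivalent by construction to a naive full scan.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("reference contains no sequences")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self._encoded = {
            name: _encode(seq, _REF_ENCODE) for name, seq in self.sequences.items()
        }
        self._cache: dict[tuple[str, int, bool], list[AlignmentRecord]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceIndex":
        return cls(read_fasta(path))

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def _scan(self, query: np.ndarray, max_mismatches: int) -> list[tuple[str, int, int]]:
        """(chrom, start, mismatches) for every window within the threshold."""
        L = len(query)
        hits: list[tuple[str, int, int]] = []
        for chrom in sorted(self._encoded):
            ref = self._encoded[chrom]
            if L > len(ref):
                continue
            windows = sliding_window_view(ref, L)
            mm = np.count_nonzero(windows != query, axis=1)
            for start in np.nonzero(mm <= max_mismatches)[0]:
                hits.append((chrom, int(start), int(mm[start])))
        return hits


def align_exhaustive(
    read: SmallRead,
    index: ReferenceIndex,
    max_mismatches: int,
    report_all: bool,
) -> list[AlignmentRecord]:
    """Every (or the single best) ungapped placement of a read on both strands.

    With ``report_all`` the full list of placements at Hamming distance
    <= ``max_mismatches`` is returned, ordered by (chrom, start, strand) with
    '+' before '-'. Otherwise at most one placement with the minimum mismatch
    count is returned, ties resolved by that same ordering. Reverse-strand
    hits compare the read's reverse complement against the forward reference,
    with coordinates reported on the forward strand.
    """
    if not read.sequence:
        raise ValueError(f"read {read.read_id!r} is empty")
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be in {0, 1, 2}")

    key = (read.sequence, max_mismatches, report_all)
    cached = index._cache.get(key)
    if cached is not None:
        return [
            AlignmentRecord(read.read_id, a.chrom, a.start, a.end, a.strand,
                            a.n_mismatches, a.sequence)
            for a in cached
        ]

    L = len(read.sequence)
    fwd = _encode(read.sequence, _READ_ENCODE)
    rev = _encode(reverse_complement(read.sequence), _READ_ENCODE)
    placements: list[tuple[str, int, str, int]] = []
    for chrom, start, mm in index._scan(fwd, max_mismatches):
        placements.append((chrom, start, "+", mm))
    for chrom, start, mm in index._scan(rev, max_mismatches):
        placements.append((chrom, start, "-", mm))
    placements.sort(key=lambda t: (t[0], t[1], t[2]))  # '+' < '-' in ASCII

    if not report_all and placements:
        placements = [min(placements, key=lambda t: (t[3], t[0], t[1], t[2]))]

    records = [
        AlignmentRecord(
            read_id=read.read_id,
            chrom=chrom,
            start=start,
            end=start + L,
            strand=strand,
            n_mismatches=mm,
            sequence=read.sequence,
        )
        for chrom, start, strand, mm in placements
    ]
    index._cache[key] = records
    return records


@dataclass
class RrnaFilterResult:
    kept: list[SmallRead]
    removed: int


def filter_rrna(
    reads: Iterable[SmallRead],
    rrna_index: ReferenceIndex,
    max_mismatches: int = DEFAULT_RRNA_MISMATCHES,
) -> RrnaFilterResult:
    """Drop reads that align to the rRNA reference within the mismatch budget.

    rRNA degradation products dominate contamination in small-RNA libraries;
    the permissive two-mismatch threshold removes them even with sequencing
    errors. Only the mapped/unmapped decision is used — the placement itself
    is discarded (best-hit-only semantics).
    """
    kept: list[SmallRead] = []
    removed = 0
    for read in reads:
        if align_exhaustive(read, rrna_index, max_mismatches, report_all=False):
            removed += 1
        else:
            kept.append(read)
    return RrnaFilterResult(kept=kept, removed=removed)


def select_genome_alignments(
    read: SmallRead,
    genome_index: ReferenceIndex,
    max_loci: int = DEFAULT_MAX_LOCI,
) -> tuple[Optional[ReadAlignmentSet], str]:
    """Zero-mismatch genome placements of a read, with the multimapper cap.

    Returns ``(set, 'mapped')`` when the read has between 1 and ``max_loci``
    exact placements, ``(None, 'unmapped')`` with none, and
    ``(None, 'suppressed')`` with more than ``max_loci`` — matching bowtie's
    ``-m`` semantics (suppress only when strictly more than the cap, so a
    read with exactly ``max_loci`` placements is retained).
    """
    if max_loci < 1:
        raise ValueError("max_loci must be >= 1")
    alignments = align_exhaustive(read, genome_index, max_mismatches=0, report_all=True)
    if not alignments:
        return None, "unmapped"
    if len(alignments) > max_loci:
        return None, "suppressed"
    return ReadAlignmentSet(read_id=read.read_id, read=read, alignments=alignments), "mapped"
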
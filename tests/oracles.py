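"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code: the
alignment oracle scans by position-shifted array comparison (the library
uses a sliding-window view), the tiny-genome oracle is pure Python, the
trimming oracle enumerates every (position, prefix-length) pair, and the
classification oracle linearly scans every feature of every class.
"""

from __future__ import annotations

import math

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_one_strand(ref: str, query: str, max_mm: int) -> list[tuple[int, int]]:
    """(start, mismatches) via per-offset shifted comparison; N never matches."""
    L, N = len(query), len(ref)
    if L > N:
        return []
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    # remap N so reference N != read N
    ref_arr[ref_arr == ord("N")] = 1
    q_arr = q_arr.copy()
    q_arr[q_arr == ord("N")] = 2
    mm = np.zeros(N - L + 1, dtype=np.int32)
    for j in range(L):
        mm += ref_arr[j : j + N - L + 1] != q_arr[j]
    return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mm)[0]]


def naive_alignments(
    genome: dict[str, str], read_seq: str, max_mm: int
) -> list[tuple[str, int, str, int]]:
    """All (chrom, start, strand, mismatches) placements, sorted."""
    hits = []
    for chrom, ref in genome.items():
        for start, mm in _scan_one_strand(ref.upper(), read_seq.upper(), max_mm):
            hits.append((chrom, start, "+", mm))
        for start, mm in _scan_one_strand(ref.upper(), revcomp(read_seq.upper()), max_mm):
            hits.append((chrom, start, "-", mm))
    return sorted(hits)


def naive_alignments_python(
    genome: dict[str, str], read_seq: str, max_mm: int
) -> list[tuple[str, int, str, int]]:
    """Pure-Python window scan for tiny genomes; cross-checks the numpy oracle."""

    def mm_count(a: str, b: str) -> int:
        return sum(1 if (x != y or x == "N") else 0 for x, y in zip(a, b))

    hits = []
    L = len(read_seq)
    for chrom, ref in genome.items():
        ref = ref.upper()
        for query, strand in ((read_seq.upper(), "+"), (revcomp(read_seq.upper()), "-")):
            for start in range(len(ref) - L + 1):
                mm = mm_count(ref[start : start + L], query)
                if mm <= max_mm:
                    hits.append((chrom, start, strand, mm))
    return sorted(hits)


def min_two_strand_distance(genome: dict[str, str], read_seq: str) -> int:
    """Smallest Hamming distance of the read to any window on either strand."""
    best = len(read_seq) + 1
    read = read_seq.upper()
    for chrom, ref in genome.items():
        ref = ref.upper()
        for query in (read, revcomp(read)):
            for start, mm in _scan_one_strand(ref, query, best):
                best = min(best, mm)
    return best


def brute_force_trim(seq: str, adapter: str, max_error_rate: float, min_overlap: int):
    """Best (mismatches, position) over every (p, L) adapter-prefix candidate.

    Returns None when no candidate is within tolerance.
    """
    n, alen = len(seq), len(adapter)
    best = None
    for p in range(n):
        for L in range(min_overlap, alen + 1):
            if p + L > n:
                continue
            reaches_end = p + L == n
            if not reaches_end and L != alen:
                continue
            mm = sum(1 for a, b in zip(adapter[:L], seq[p : p + L]) if a != b)
            if mm <= math.floor(max_error_rate * L):
                cand = (mm, p)
                if best is None or cand < best:
                    best = cand
    return best


def brute_force_classify(aln, features, order, min_overlap_frac: float):
    """Linear scan over *all* features of *all* classes with the tier rules.

    ``features`` maps BED class -> list of FeatureInterval (TE listed once).
    """
    aln_len = aln.end - aln.start
    for tier in order:
        bed_class = "TE" if tier in ("TE_sense", "TE_antisense") else tier
        candidates = []
        for feature in features.get(bed_class, []):
            if feature.chrom != aln.chrom:
                continue
            overlap = min(aln.end, feature.end) - max(aln.start, feature.start)
            if overlap < min_overlap_frac * aln_len:
                continue
            if tier == "piRNA_cluster":
                ok = True
            elif tier == "TE_antisense":
                ok = aln.strand != feature.strand
            else:
                ok = aln.strand == feature.strand
            if ok:
                candidates.append((-overlap, feature.feature_id))
        if candidates:
            return tier, min(candidates)[1]
    return None
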
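"""Priority decision-tree classification of alignments across sRNA classes.

Each alignment is tested against ordered annotation tiers; the first tier
with a qualifying overlap claims it, so e.g. a read from an intronic miRNA
is labeled miRNA, not intron. The default order is structural RNAs, mature
miRNAs, hairpins, exons, sense TEs, antisense TEs, introns, piRNA clusters;
the order is user-configurable.

Strand rules per tier: structural_RNA, miRNA, hairpin, exon and intron
require the alignment on the feature's strand (sRNA biogenesis is
sense-stranded for these classes); TE_sense requires equal strands and
TE_antisense opposite strands (the two tiers share one TE annotation set);
piRNA_cluster accepts either strand, since clusters are often bidirectional.

A feature qualifies when it covers at least ``min_overlap_frac`` (default
0.5) of the alignment's length. Within a tier the feature with the largest
overlap wins, ties broken by lexicographically smallest feature id — the
outcome is deterministic and independent of annotation file order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .alignment import ReadAlignmentSet
from .sequence_io import AlignmentRecord, FeatureInterval, read_bed

logger = logging.getLogger(__name__)

#: Tier labels understood by the classifier.
TIER_LABELS = (
    "structural_RNA",
    "miRNA",
    "hairpin",
    "exon",
    "TE_sense",
    "TE_antisense",
    "intron",
    "piRNA_cluster",
)

DEFAULT_ORDER = list(TIER_LABELS)
DEFAULT_MIN_OVERLAP_FRAC = 0.5


def _bed_class(tier: str) -> str:
    """Annotation-file class backing a tier (the two TE tiers share one file)."""
    return "TE" if tier in ("TE_sense", "TE_antisense") else tier


@dataclass
class PriorityOrder:
    """Ordered annotation tiers for the decision tree."""

    tiers: list[str] = field(default_factory=lambda: list(DEFAULT_ORDER))

    def __post_init__(self) -> None:
        if len(set(self.tiers)) != len(self.tiers):
            raise ValueError("priority order contains duplicate tiers")
        unknown = [t for t in self.tiers if t not in TIER_LABELS]
        if unknown:
            raise ValueError(f"unknown tier labels: {unknown}")
        if "TE_sense" in self.tiers and "TE_antisense" in self.tiers:
            if self.tiers.index("TE_sense") > self.tiers.index("TE_antisense"):
                raise ValueError("TE_sense must precede TE_antisense")

    @classmethod
    def from_string(cls, spec: str) -> "PriorityOrder":
        return cls([t.strip() for t in spec.split(",") if t.strip()])

    def __iter__(self):
        return iter(self.tiers)

    def __len__(self) -> int:
        return len(self.tiers)


@dataclass(frozen=True)
class AnnotatedAlignment:
    """An alignment stamped with its winning class and 1/n weight."""

    alignment: AlignmentRecord
    class_label: str
    feature_id: str
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight {self.weight} outside (0, 1]")
        if self.class_label not in TIER_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}")


class AnnotationDB:
    """Per-class interval indices over the annotation sets.

    TE intervals are stored once; the sense/antisense split is resolved
    against the alignment strand at query time. Overlap queries are answered
    by interval trees and return exactly what a linear scan would.
    """

    def __init__(self, order: Optional[PriorityOrder] = None):
        self.order = order or PriorityOrder()
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        self._features: dict[str, list[FeatureInterval]] = {}

    def add_intervals(self, class_label: str, intervals: Iterable[FeatureInterval]) -> None:
        trees = self._trees.setdefault(class_label, {})
        stored = self._features.setdefault(class_label, [])
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            stored.append(iv)

    def has_class(self, class_label: str) -> bool:
        return class_label in self._trees

    def features(self, class_label: str) -> list[FeatureInterval]:
        return list(self._features.get(class_label, []))

    def all_features(self) -> list[FeatureInterval]:
        return [iv for ivs in self._features.values() for iv in ivs]

    def query(self, class_label: str, chrom: str, start: int, end: int) -> list[FeatureInterval]:
        """Features of a class overlapping [start, end) on chrom, by >= 1 bp."""
        trees = self._trees.get(class_label)
        if not trees or chrom not in trees:
            return []
        return [hit.data for hit in trees[chrom].overlap(start, end)]


def build_annotation_db(
    bed_paths: dict[str, str | Path],
    order: Optional[PriorityOrder] = None,
) -> AnnotationDB:
    """Load per-class BED6 files into interval indices.

    ``bed_paths`` is keyed by annotation class (``TE`` serves both the
    TE_sense and TE_antisense tiers). A missing file skips that tier with a
    warning; a malformed file propagates its parse error.
    """
    db = AnnotationDB(order=order)
    needed = {_bed_class(t) for t in db.order}
    for class_label in sorted(needed):
        path = bed_paths.get(class_label)
        if path is None or not Path(path).exists():
            logger.warning("annotation for class %r missing; tier skipped", class_label)
            continue
        db.add_intervals(class_label, read_bed(path, class_label))
    return db


def _strand_ok(tier: str, aln_strand: str, feature_strand: str) -> bool:
    if tier == "piRNA_cluster":
        return True
    if tier == "TE_antisense":
        return aln_strand != feature_strand
    return aln_strand == feature_strand


def classify_alignment(
    aln: AlignmentRecord,
    db: AnnotationDB,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> Optional[tuple[str, str]]:
    """Walk the priority tiers and return ``(class_label, feature_id)``.

    The first tier containing a feature that overlaps the alignment by at
    least ``min_overlap_frac`` of the alignment's length *and* satisfies the
    tier's strand rule wins; ``None`` means no tier claimed the alignment.
    """
    if not (0.0 < min_overlap_frac <= 1.0):
        raise ValueError("min_overlap_frac must be in (0, 1]")
    aln_len = aln.end - aln.start
    min_overlap = min_overlap_frac * aln_len
    for tier in db.order:
        candidates: list[tuple[int, str]] = []
        for feature in db.query(_bed_class(tier), aln.chrom, aln.start, aln.end):
            if not _strand_ok(tier, aln.strand, feature.strand):
                continue
            overlap = min(aln.end, feature.end) - max(aln.start, feature.start)
            if overlap >= min_overlap:
                candidates.append((overlap, feature.feature_id))
        if candidates:
            candidates.sort(key=lambda c: (-c[0], c[1]))
            return tier, candidates[0][1]
    return None


@dataclass
class AnnotationResult:
    """Annotated alignments of a library plus the per-class weight tallies."""

    annotated: list[AnnotatedAlignment]
    class_weights: dict[str, float]
    unannotated_alignments: int


def annotate_library(
    sets: Iterable[ReadAlignmentSet],
    db: AnnotationDB,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> AnnotationResult:
    """Classify every alignment of every read set and attach 1/n weights.

    ``n`` is fixed at alignment selection, before annotation, so a
    multimapper whose placements land in different classes (or partly in
    none) still contributes at most a total weight of 1. Unclassified
    alignments are tallied but not emitted.
    """
    annotated: list[AnnotatedAlignment] = []
    per_class: dict[str, list[float]] = {}
    unannotated = 0
    for aset in sets:
        weight = 1.0 / aset.n
        for aln in aset.alignments:
            hit = classify_alignment(aln, db, min_overlap_frac)
            if hit is None:
                unannotated += 1
                continue
            class_label, feature_id = hit
            annotated.append(
                AnnotatedAlignment(
                    alignment=aln,
                    class_label=class_label,
                    feature_id=feature_id,
                    weight=weight,
                )
            )
            per_class.setdefault(class_label, []).append(weight)
    # exact summation so tallies agree with the count table to < 1e-9
    class_weights = {c: math.fsum(ws) for c, ws in per_class.items()}
    return AnnotationResult(
        annotated=annotated,
        class_weights=class_weights,
        unannotated_alignments=unannotated,
    )
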
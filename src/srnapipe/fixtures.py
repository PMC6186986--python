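"""Deterministic synthetic reference and labeled read simulator.

Everything here is synthetic: a toy two-chromosome genome (~35 kb) with
planted, non-overlapping features of every annotation class, decoy rRNA
sequences, and a read simulator that records ground truth for every read.
This lets every pipeline stage — and the end-to-end run — be tested without
downloading a real genome or annotation bundle.

The reference always contains the two structurally interesting cases:

* a mature miRNA nested inside a hairpin nested inside an intron, the case
  the priority decision tree exists for;
* planted exact-copy repeat families of 100 and 150 copies, straddling the
  default multimapper cap of 100 (retained at exactly 100, suppressed at
  150).

Sampling regions are chosen so each simulated read unambiguously belongs to
its truth class under the default classifier settings (e.g. hairpin reads
are drawn outside the mature miRNA annotation, intron reads outside the
nested hairpin). Reads are sequencing-error-free by default; rRNA decoys can
carry a configurable number of substitutions to exercise the contaminant
filter's mismatch tolerance. At the zero-mismatch genome stage any
substitution simply unmaps a read, so no genome-stage error model exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER
from .sequence_io import (
    FeatureInterval,
    SmallRead,
    reverse_complement,
    write_bed,
    write_fasta,
    write_fastq,
)

BASES = np.array(list("ACGT"))

#: Insert-length distribution over 18-30 nt with a mode at 22 nt, loosely
#: shaped like a real miRNA-dominated small-RNA library.
INSERT_LENGTHS = np.arange(18, 31)
_INSERT_WEIGHTS = np.array([2, 4, 7, 12, 20, 12, 7, 4, 3, 2, 2, 1, 1], dtype=float)
INSERT_PROBS = _INSERT_WEIGHTS / _INSERT_WEIGHTS.sum()

#: Default class mix for simulated libraries: miRNA-dominated, with TE
#: siRNAs the next largest group, plus small rRNA/decoy/repeat fractions.
DEFAULT_CLASS_MIX = {
    "structural_RNA": 0.08,
    "miRNA": 0.25,
    "hairpin": 0.07,
    "exon": 0.12,
    "TE_sense": 0.15,
    "TE_antisense": 0.10,
    "intron": 0.08,
    "piRNA_cluster": 0.08,
    "rRNA": 0.04,
    "unmappable": 0.01,
    "repeat_100": 0.01,
    "repeat_150": 0.01,
}


@dataclass(frozen=True)
class SamplingRegion:
    """A genomic window from which reads of one truth class may be drawn."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class RepeatFamily:
    name: str
    unit: str
    intervals: list[FeatureInterval]

    @property
    def copies(self) -> int:
        return len(self.intervals)


@dataclass
class ToyReference:
    genome: dict[str, str]
    rrna: dict[str, str]
    features: dict[str, list[FeatureInterval]]  # keyed by BED class
    repeat_families: dict[str, RepeatFamily]
    sampling_regions: dict[str, list[SamplingRegion]]  # keyed by truth class
    planted: dict[str, str]  # feature_id -> genome-forward sequence

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit genome.fa, rrna.fa and one BED6 file per annotation class."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = out_dir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        paths["rrna"] = out_dir / "rrna.fa"
        write_fasta(self.rrna, paths["rrna"])
        for class_label, intervals in self.features.items():
            path = out_dir / f"{class_label}.bed"
            write_bed(intervals, path)
            paths[class_label] = path
        return paths


class _ChromBuilder:
    """Appends filler and planted blocks, tracking coordinates."""

    def __init__(self, name: str, rng: np.random.Generator):
        self.name = name
        self.rng = rng
        self.parts: list[str] = []
        self.length = 0

    def filler(self, lo: int, hi: int) -> None:
        n = int(self.rng.integers(lo, hi + 1))
        self.plant(_random_seq(self.rng, n))

    def plant(self, seq: str) -> int:
        start = self.length
        self.parts.append(seq)
        self.length += len(seq)
        return start

    def sequence(self) -> str:
        return "".join(self.parts)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def generate_toy_reference(seed: int) -> ToyReference:
    """Build the deterministic toy genome, rRNA decoys and annotations.

    The same seed always produces byte-identical files. Unique-locus
    features get independent random sequences, so (at these lengths) no
    simulated read maps anywhere but its source, while the repeat families
    are exact copies of one unit each.
    """
    # distinct spawn key so a library simulated with the same integer seed
    # draws from an independent stream (otherwise "random" decoy reads can
    # replay the very bytes that became genome filler)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    features: dict[str, list[FeatureInterval]] = {
        c: [] for c in ("structural_RNA", "miRNA", "hairpin", "exon", "TE",
                        "intron", "piRNA_cluster")
    }
    sampling: dict[str, list[SamplingRegion]] = {
        c: [] for c in ("structural_RNA", "miRNA", "hairpin", "exon", "TE_sense",
                        "TE_antisense", "intron", "piRNA_cluster")
    }
    planted: dict[str, str] = {}

    chrom1 = _ChromBuilder("chr1", rng)
    chrom1.filler(250, 350)

    def add_feature(builder, class_label, feature_id, length, strand):
        seq = _random_seq(rng, length)
        start = builder.plant(seq)
        iv = FeatureInterval(feature_id, class_label, builder.name, start, start + length, strand)
        features[class_label].append(iv)
        planted[feature_id] = seq
        return iv

    # Unique structural-RNA loci (tRNA/snoRNA stand-ins).
    for i, strand in enumerate("+-+-"):
        iv = add_feature(chrom1, "structural_RNA", f"structRNA-{i + 1}", 90, strand)
        sampling["structural_RNA"].append(
            SamplingRegion(iv.feature_id, iv.chrom, iv.start, iv.end, iv.strand))
        chrom1.filler(150, 300)

    # The canonical nesting case: mature miRNA inside a hairpin inside an intron.
    intron_seq = _random_seq(rng, 600)
    intron_start = chrom1.plant(intron_seq)
    hp_start = intron_start + 100
    mat_start = hp_start + 10
    features["intron"].append(
        FeatureInterval("intron-nest", "intron", "chr1", intron_start, intron_start + 600, "+"))
    features["hairpin"].append(
        FeatureInterval("hairpin-nest", "hairpin", "chr1", hp_start, hp_start + 80, "+"))
    features["miRNA"].append(
        FeatureInterval("mir-nest", "miRNA", "chr1", mat_start, mat_start + 22, "+"))
    planted["intron-nest"] = intron_seq
    planted["hairpin-nest"] = intron_seq[100:180]
    planted["mir-nest"] = intron_seq[110:132]
    sampling["miRNA"].append(SamplingRegion("mir-nest", "chr1", mat_start, mat_start + 22, "+"))
    # hairpin reads drawn downstream of the mature annotation
    sampling["hairpin"].append(
        SamplingRegion("hairpin-nest", "chr1", hp_start + 32, hp_start + 80, "+"))
    # intron reads drawn clear of the nested hairpin
    sampling["intron"].append(
        SamplingRegion("intron-nest", "chr1", intron_start + 220, intron_start + 600, "+"))
    chrom1.filler(150, 300)

    # Standalone miRNA/hairpin pairs: mature at offset 8, 22 nt.
    for i, strand in enumerate("+-+"):
        hp = add_feature(chrom1, "hairpin", f"hairpin-{i + 1}", 80, strand)
        mat = FeatureInterval(f"mir-{i + 1}", "miRNA", "chr1", hp.start + 8, hp.start + 30, strand)
        features["miRNA"].append(mat)
        planted[mat.feature_id] = planted[hp.feature_id][8:30]
        sampling["miRNA"].append(
            SamplingRegion(mat.feature_id, "chr1", mat.start, mat.end, strand))
        sampling["hairpin"].append(
            SamplingRegion(hp.feature_id, "chr1", mat.end, hp.end, strand))
        chrom1.filler(150, 300)

    for i, strand in enumerate("+-+-"):
        iv = add_feature(chrom1, "exon", f"exon-{i + 1}", 200, strand)
        sampling["exon"].append(
            SamplingRegion(iv.feature_id, iv.chrom, iv.start, iv.end, iv.strand))
        chrom1.filler(150, 300)

    # Unique TEs on both strands; the same loci serve sense and antisense reads.
    for i, strand in enumerate("+-+-+-"):
        iv = add_feature(chrom1, "TE", f"TE-{i + 1}", 350, strand)
        sampling["TE_sense"].append(
            SamplingRegion(iv.feature_id, iv.chrom, iv.start, iv.end, iv.strand))
        anti = "-" if strand == "+" else "+"
        sampling["TE_antisense"].append(
            SamplingRegion(iv.feature_id, iv.chrom, iv.start, iv.end, anti))
        chrom1.filler(150, 300)

    for i, strand in enumerate("+-"):
        iv = add_feature(chrom1, "intron", f"intron-{i + 1}", 400, strand)
        sampling["intron"].append(
            SamplingRegion(iv.feature_id, iv.chrom, iv.start, iv.end, iv.strand))
        chrom1.filler(150, 300)

    for i, strand in enumerate("+-"):
        iv = add_feature(chrom1, "piRNA_cluster", f"piCluster-{i + 1}", 1000, strand)
        sampling["piRNA_cluster"].append(
            SamplingRegion(iv.feature_id, iv.chrom, iv.start, iv.end, iv.strand))
        chrom1.filler(150, 300)

    # chr2: exact-copy repeat families straddling the multimapper cap.
    chrom2 = _ChromBuilder("chr2", rng)
    chrom2.filler(200, 300)
    repeat_families: dict[str, RepeatFamily] = {}
    for name, copies, annotate in (("repeat_100", 100, True), ("repeat_150", 150, False)):
        unit = _random_seq(rng, 60)
        intervals = []
        for i in range(copies):
            start = chrom2.plant(unit)
            iv = FeatureInterval(f"{name}_c{i + 1:03d}", "TE", "chr2", start, start + 60, "+")
            intervals.append(iv)
            if annotate:
                features["TE"].append(iv)
                planted[iv.feature_id] = unit
            chrom2.filler(18, 30)
        repeat_families[name] = RepeatFamily(name, unit, intervals)
        chrom2.filler(250, 400)

    genome = {"chr1": chrom1.sequence(), "chr2": chrom2.sequence()}
    rrna = {
        "rRNA_5S_synthetic": _random_seq(rng, 400),
        "rRNA_58S_synthetic": _random_seq(rng, 500),
        "rRNA_18S_synthetic": _random_seq(rng, 600),
    }
    return ToyReference(
        genome=genome,
        rrna=rrna,
        features=features,
        repeat_families=repeat_families,
        sampling_regions=sampling,
        planted=planted,
    )


@dataclass
class LabeledReadSet:
    """Simulated reads plus the per-read ground truth."""

    reads: list[SmallRead]
    truth: pd.DataFrame  # columns: read_id, true_class, feature_id, n_expected
    adapter: str
    fastq: Optional[Path] = None
    truth_path: Optional[Path] = None

    def write(self, out_dir: str | Path, gzip_fastq: bool = True) -> "LabeledReadSet":
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.fastq = out_dir / ("reads.fastq.gz" if gzip_fastq else "reads.fastq")
        write_fastq(self.reads, self.fastq)
        self.truth_path = out_dir / "truth.tsv"
        self.truth.to_csv(self.truth_path, sep="\t", index=False)
        return self


def _allocate_counts(n_reads: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so class counts are exact and sum to n."""
    items = sorted(mix.items())
    raw = [n_reads * frac for _, frac in items]
    base = [math.floor(x) for x in raw]
    shortfall = n_reads - sum(base)
    by_remainder = sorted(
        range(len(items)), key=lambda i: (-(raw[i] - base[i]), items[i][0])
    )
    for i in by_remainder[:shortfall]:
        base[i] += 1
    return {items[i][0]: base[i] for i in range(len(items))}


def simulate_reads(
    ref: ToyReference,
    n_reads: int,
    class_mix: Optional[dict[str, float]] = None,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    rrna_substitutions: int = 0,
) -> LabeledReadSet:
    """Draw labeled reads from the toy reference and append the 3' adapter.

    ``class_mix`` maps truth labels to fractions summing to 1. Labels are the
    eight annotation tiers plus ``rRNA`` (contaminant decoys, optionally with
    up to ``rrna_substitutions`` random substitutions each), ``unmappable``
    (random sequence), and ``repeat_100`` / ``repeat_150`` (reads from the
    planted repeat families; the former are genuine TE multimappers with 100
    placements, the latter exceed the default cap and should be suppressed).
    Inserts are 18-30 nt (mode 22), clipped to their source region; the full
    adapter is appended. Class counts are exact (largest-remainder), and the
    same seed yields byte-identical output.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    total = math.fsum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix fractions sum to {total}, not 1")
    known = set(ref.sampling_regions) | {"rRNA", "unmappable", "repeat_100", "repeat_150"}
    unknown = set(mix) - known
    if unknown:
        raise ValueError(f"unknown class_mix labels: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    counts = _allocate_counts(n_reads, mix)
    labels = np.repeat(
        [label for label in sorted(counts)],
        [counts[label] for label in sorted(counts)],
    )
    rng.shuffle(labels)

    rrna_names = sorted(ref.rrna)
    reads: list[SmallRead] = []
    truth_rows: list[tuple[str, str, str, int]] = []
    for i, label in enumerate(labels):
        read_id = f"r{i + 1:06d}"
        draw = int(rng.choice(INSERT_LENGTHS, p=INSERT_PROBS))
        if label == "rRNA":
            name = rrna_names[int(rng.integers(len(rrna_names)))]
            src = ref.rrna[name]
            start = int(rng.integers(0, len(src) - draw + 1))
            insert = _substitute(rng, src[start : start + draw], rrna_substitutions)
            feature_id, n_expected = name, 0
        elif label == "unmappable":
            insert = _random_seq(rng, draw)
            feature_id, n_expected = "random", 0
        elif label in ("repeat_100", "repeat_150"):
            family = ref.repeat_families[label]
            length = min(draw, len(family.unit))
            start = int(rng.integers(0, len(family.unit) - length + 1))
            insert = family.unit[start : start + length]
            feature_id, n_expected = family.name, family.copies
        else:
            regions = ref.sampling_regions[label]
            region = regions[int(rng.integers(len(regions)))]
            length = min(draw, region.end - region.start)
            start = int(rng.integers(region.start, region.end - length + 1))
            fragment = ref.genome[region.chrom][start : start + length]
            if label == "piRNA_cluster":
                read_strand = "+" if rng.integers(2) == 0 else "-"
            else:
                read_strand = region.strand
            insert = fragment if read_strand == "+" else reverse_complement(fragment)
            feature_id, n_expected = region.feature_id, 1
        sequence = insert + adapter
        reads.append(SmallRead(read_id, sequence, "I" * len(sequence)))
        truth_rows.append((read_id, str(label), feature_id, n_expected))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "true_class", "feature_id", "n_expected"]
    )
    return LabeledReadSet(reads=reads, truth=truth, adapter=adapter)


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs <= 0:
        return seq
    n_subs = min(n_subs, len(seq))
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)
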
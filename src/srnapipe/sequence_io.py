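"""Readers and writers for the formats the pipeline touches, plus core record types.

Coordinates are 0-based half-open everywhere in memory; the 1-based closed
convention of SAM POS exists only at the SAM boundary (pysam handles it).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Annotation classes as they appear in BED inputs. Transposable elements are
#: stored once and split into sense/antisense tiers at classification time.
BED_CLASSES = (
    "structural_RNA",
    "miRNA",
    "hairpin",
    "exon",
    "TE",
    "intron",
    "piRNA_cluster",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed record in an input file, with enough context to locate it."""


@dataclass
class SmallRead:
    """One small-RNA sequencing read flowing through trimming and filtering.

    ``qualities`` may be empty when absent (e.g. FASTA-derived reads); when
    non-empty it must match the sequence length. An empty sequence is legal
    only as the output of adapter trimming (a pure adapter-dimer read); such
    reads are removed by the length filter.
    """

    read_id: str
    sequence: str
    qualities: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureInterval:
    """A strand-aware genomic interval belonging to one annotation class."""

    feature_id: str
    class_label: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One ungapped placement of a read on the reference.

    Coordinates are on the forward strand of ``chrom``; ``strand == '-'``
    means the reverse complement of the read matches there.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"alignment of {self.read_id!r}: span {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment of {self.read_id!r}: strand {self.strand!r}")
        if self.n_mismatches < 0:
            raise ValueError("negative mismatch count")

    def __len__(self) -> int:
        return self.end - self.start


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[SmallRead]:
    """Yield one :class:`SmallRead` per 4-line FASTQ record, order preserved.

    Plain and gzip-compressed files are detected by magic bytes. Malformed
    records raise :class:`ParseError` naming the (0-based) record index.
    """
    with _open_text(path) as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"record {record_idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ParseError(f"record {record_idx}: separator line missing '+'")
            if not seq:
                raise ParseError(f"record {record_idx}: empty sequence")
            if len(seq) != len(qual):
                raise ParseError(
                    f"record {record_idx}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            yield SmallRead(read_id, seq, qual)
            record_idx += 1


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        # fixed mtime so identical inputs give byte-identical files
        with open(path, "wb") as raw, gzip.GzipFile(
            fileobj=raw, mode="wb", mtime=0
        ) as gz:
            for read in reads:
                qual = read.qualities or "I" * len(read.sequence)
                gz.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n".encode())
        return
    with open(path, "wt") as fh:
        for read in reads:
            qual = read.qualities or "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Name → uppercase sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path, class_label: str) -> list[FeatureInterval]:
    """Parse a BED6 file into :class:`FeatureInterval` objects of one class.

    The score column is ignored. A '.' strand is rejected (line dropped with
    a warning) for class TE, where sense/antisense classification makes an
    unstranded feature meaningless, and coerced to '+' with a warning for
    every other class.
    """
    if class_label not in BED_CLASSES:
        raise ValueError(f"unknown annotation class {class_label!r}")
    intervals: list[FeatureInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path} line {lineno}: expected 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path} line {lineno}: bad strand {strand!r}")
            if strand == ".":
                if class_label == "TE":
                    logger.warning(
                        "%s line %d: '.' strand rejected for TE feature %s",
                        path, lineno, name,
                    )
                    continue
                logger.warning(
                    "%s line %d: '.' strand coerced to '+' for %s feature %s",
                    path, lineno, class_label, name,
                )
                strand = "+"
            intervals.append(FeatureInterval(name, class_label, chrom, start, end, strand))
    return intervals


def write_bed(intervals: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.feature_id}\t0\t{iv.strand}\n"
            )


class UnsupportedAlignmentError(ValueError):
    """A SAM record whose CIGAR is not a single ungapped match."""


def read_sam_alignments(path: str | Path):
    """Ingest ungapped SAM alignments, grouped per read into alignment sets.

    Accepts output of any external ungapped aligner; every mapped record must
    have a CIGAR of the form ``<L>M`` (insertions, deletions, splices or
    clipping raise :class:`UnsupportedAlignmentError`). Unmapped records are
    skipped. Reads with at least one mapped record come back as
    :class:`~srnapipe.alignment.ReadAlignmentSet` objects with ``n`` equal to
    their mapped-record count, in order of first appearance.
    """
    from .alignment import ReadAlignmentSet  # local import to avoid a cycle

    by_read: dict[str, list[AlignmentRecord]] = {}
    read_seqs: dict[str, SmallRead] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cigar = rec.cigartuples or []
            if len(cigar) != 1 or cigar[0][0] != 0:  # 0 == M
                raise UnsupportedAlignmentError(
                    f"read {rec.query_name!r} at {rec.reference_name}:"
                    f"{rec.reference_start}: unsupported CIGAR {rec.cigarstring!r}"
                )
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or ""
            # SAM stores the reference-forward orientation; recover the read
            # as sequenced so downstream records agree with the FASTQ.
            read_seq = reverse_complement(seq) if strand == "-" else seq
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            aln = AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_start + len(seq),
                strand=strand,
                n_mismatches=int(nm),
                sequence=read_seq,
            )
            by_read.setdefault(rec.query_name, []).append(aln)
            read_seqs.setdefault(rec.query_name, SmallRead(rec.query_name, read_seq))
    return [
        ReadAlignmentSet(read_id=rid, read=read_seqs[rid], alignments=alns)
        for rid, alns in by_read.items()
    ]


def write_sam_alignments(sets, path: str | Path, reference_lengths: dict[str, int]) -> None:
    """Write alignment sets as a headered SAM file (ungapped M CIGARs only)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aset in sets:
            for aln in aset.alignments:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = aln.read_id
                rec.flag = 16 if aln.strand == "-" else 0
                rec.reference_id = out.header.get_tid(aln.chrom)
                rec.reference_start = aln.start
                rec.mapping_quality = 255
                rec.cigartuples = [(0, len(aln.sequence))]
                rec.query_sequence = (
                    reverse_complement(aln.sequence) if aln.strand == "-" else aln.sequence
                )
                rec.set_tag("NM", aln.n_mismatches)
                out.write(rec)


def write_counts_tsv(table, path: str | Path, rounding: str = "none") -> None:
    """Write a count table as a flat TSV ready for differential analysis.

    Header is ``feature_id<TAB>class<TAB><sample...>``; rows are sorted by
    (class, feature_id) for determinism. ``rounding='none'`` writes fractional
    1/n-weighted values at fixed 6-decimal precision; ``'nearest-integer'``
    rounds to integers for count-based statistics packages that require them.
    """
    if rounding not in ("none", "nearest-integer"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    df = table.to_frame()
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample names in count table")
    df = df.reindex(sorted(df.index, key=lambda key: (key[1], key[0])))
    with open(path, "wt") as fh:
        fh.write("feature_id\tclass\t" + "\t".join(map(str, df.columns)) + "\n")
        for (feature_id, class_label), row in df.iterrows():
            if rounding == "nearest-integer":
                cells = [str(int(round(v))) for v in row]
            else:
                cells = [f"{v:.6f}" for v in row]
            fh.write(f"{feature_id}\t{class_label}\t" + "\t".join(cells) + "\n")


def read_counts_tsv(path: str | Path):
    """Re-read a counts TSV written by :func:`write_counts_tsv`."""
    from .quantify import CountTable

    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "class": str})
    df = df.set_index(["feature_id", "class"])
    df.index.names = ["feature_id", "class_label"]
    return CountTable(df)
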
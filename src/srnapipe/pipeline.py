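"""One-command orchestration: trim -> size-select -> rRNA-filter -> align ->
annotate -> count -> report, per sample, then merge into one DE-ready table.

Samples are processed independently (results are identical regardless of
order) and the whole run is deterministic: identical inputs and config give
byte-identical counts.tsv and report.json.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import alignment, annotation, preprocess, quantify, report, sequence_io

logger = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    sample_id: str
    fastq: Path
    sam: Optional[Path] = None  # pre-computed ungapped alignments, bypassing the aligner


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    genome_fasta: Path
    rrna_fasta: Path
    bed_paths: dict[str, Path]  # annotation class -> BED6 path
    out_dir: Path
    adapter: str = preprocess.DEFAULT_ADAPTER
    max_error_rate: float = preprocess.DEFAULT_ERROR_RATE
    min_overlap: int = preprocess.DEFAULT_MIN_OVERLAP
    min_len: int = preprocess.DEFAULT_MIN_LEN
    max_len: int = preprocess.DEFAULT_MAX_LEN
    rrna_max_mismatches: int = alignment.DEFAULT_RRNA_MISMATCHES
    max_loci: int = alignment.DEFAULT_MAX_LOCI
    order: annotation.PriorityOrder = field(default_factory=annotation.PriorityOrder)
    min_overlap_frac: float = annotation.DEFAULT_MIN_OVERLAP_FRAC
    min_total: int = 0  # low-abundance pre-filter; 0 disables
    rounding: str = "none"

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        seen = set()
        for spec in self.samples:
            if spec.sample_id in seen:
                raise ValueError(f"duplicate sample id {spec.sample_id!r}")
            seen.add(spec.sample_id)
            for path in (spec.fastq, spec.sam):
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"sample {spec.sample_id}: {path}")
        for path in (self.genome_fasta, self.rrna_fasta, *self.bed_paths.values()):
            if not Path(path).exists():
                raise FileNotFoundError(str(path))
        if self.rounding not in ("none", "nearest-integer"):
            raise ValueError(f"unknown rounding {self.rounding!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        samples = [
            SampleSpec(
                sample_id=s["id"],
                fastq=resolve(s["fastq"]),
                sam=resolve(s["sam"]) if s.get("sam") else None,
            )
            for s in raw["samples"]
        ]
        kwargs = dict(
            samples=samples,
            genome_fasta=resolve(raw["genome_fasta"]),
            rrna_fasta=resolve(raw["rrna_fasta"]),
            bed_paths={c: resolve(p) for c, p in raw["annotations"].items()},
            out_dir=resolve(raw.get("out_dir", "srna_out")),
        )
        for key in (
            "adapter", "max_error_rate", "min_overlap", "min_len", "max_len",
            "rrna_max_mismatches", "max_loci", "min_overlap_frac", "min_total",
            "rounding",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "order" in raw:
            kwargs["order"] = annotation.PriorityOrder.from_string(raw["order"])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SampleResult:
    summary: report.LibrarySummary
    counts: quantify.CountTable
    alignment_sets: list


@dataclass
class PipelineResult:
    counts: quantify.CountTable
    summaries: list[report.LibrarySummary]
    outputs: dict[str, Path]


def process_sample(
    spec: SampleSpec,
    config: PipelineConfig,
    genome_index: alignment.ReferenceIndex,
    rrna_index: alignment.ReferenceIndex,
    db: annotation.AnnotationDB,
) -> SampleResult:
    funnel = report.FunnelCounts()
    trimmed: list[sequence_io.SmallRead] = []
    for read in sequence_io.read_fastq(spec.fastq):
        funnel.raw_reads += 1
        result = preprocess.trim_adapter(
            read, config.adapter, config.max_error_rate, config.min_overlap
        )
        if result.read.sequence:
            trimmed.append(result.read)
    funnel.trimmed_reads = len(trimmed)

    sized = preprocess.filter_by_length(trimmed, config.min_len, config.max_len)
    funnel.size_filtered = len(sized.kept)
    logger.info(
        "%s: %d raw, %d trimmed, %d in size range (%d short, %d long)",
        spec.sample_id, funnel.raw_reads, funnel.trimmed_reads,
        funnel.size_filtered, sized.below, sized.above,
    )

    rrna = alignment.filter_rrna(sized.kept, rrna_index, config.rrna_max_mismatches)
    funnel.rrna_removed = rrna.removed
    logger.info("%s: %d rRNA reads removed", spec.sample_id, rrna.removed)

    if spec.sam is not None:
        sets = _ingest_sam(spec, config, rrna, funnel)
    else:
        sets = []
        for read in rrna.kept:
            aset, status = alignment.select_genome_alignments(
                read, genome_index, config.max_loci
            )
            if status == "mapped":
                sets.append(aset)
                funnel.mapped += 1
            elif status == "suppressed":
                funnel.suppressed += 1
            else:
                funnel.unmapped += 1
    logger.info(
        "%s: %d mapped, %d unmapped, %d multimapper-suppressed",
        spec.sample_id, funnel.mapped, funnel.unmapped, funnel.suppressed,
    )

    annotated = annotation.annotate_library(sets, db, config.min_overlap_frac)
    summary = report.summarize_library(spec.sample_id, funnel, sets, annotated)
    counts = quantify.accumulate_counts(annotated.annotated, spec.sample_id)
    return SampleResult(summary=summary, counts=counts, alignment_sets=sets)


def _ingest_sam(spec, config, rrna, funnel):
    """External-aligner path: keep SAM alignment sets for surviving reads."""
    surviving = {read.read_id for read in rrna.kept}
    sets = []
    suppressed = 0
    seen = set()
    for aset in sequence_io.read_sam_alignments(spec.sam):
        if aset.read_id not in surviving:
            continue
        seen.add(aset.read_id)
        if aset.n > config.max_loci:
            suppressed += 1
        else:
            sets.append(aset)
    funnel.mapped = len(sets)
    funnel.suppressed = suppressed
    funnel.unmapped = len(surviving) - len(seen)
    return sets


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every sample through the full workflow and write the outputs.

    Outputs in ``config.out_dir``: counts.tsv, report.html, report.json and
    mapping_log.tsv. Any stage failure aborts the run, names the sample, and
    removes partially written outputs.
    """
    config.validate()
    genome_index = alignment.ReferenceIndex.from_fasta(config.genome_fasta)
    rrna_index = alignment.ReferenceIndex.from_fasta(config.rrna_fasta)
    db = annotation.build_annotation_db(config.bed_paths, config.order)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        results = []
        for spec in config.samples:
            try:
                results.append(
                    process_sample(spec, config, genome_index, rrna_index, db)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"sample {spec.sample_id!r} failed: {exc}"
                ) from exc

        merged = quantify.merge_samples([r.counts for r in results])
        if config.min_total > 0:
            merged = quantify.filter_low_abundance(merged, config.min_total)

        counts_path = out_dir / "counts.tsv"
        written.append(counts_path)
        sequence_io.write_counts_tsv(merged, counts_path, rounding=config.rounding)

        summaries = [r.summary for r in results]
        paths = report.render_report(summaries, out_dir)
        written.extend(paths.values())
        log_path = out_dir / "mapping_log.tsv"
        written.append(log_path)
        report.write_mapping_log(summaries, log_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    outputs = {
        "counts": counts_path,
        "report_html": paths["html"],
        "report_json": paths["json"],
        "mapping_log": log_path,
    }
    return PipelineResult(counts=merged, summaries=summaries, outputs=outputs)
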
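"""Per-library summaries and the self-contained HTML report.

The summary captures the read funnel (raw -> trimmed -> size-selected ->
rRNA-filtered -> mapped), a read-length histogram split by unique vs
multimapper status, per-class annotated weight, and the length-by-class
breakdown. The HTML report embeds static SVG charts (no network assets) and
writes a machine-readable JSON twin containing every plotted number, so the
figures are fully testable.

Conventions: the length histogram counts each read once, split by unique
(n == 1) versus multimapper (n > 1); class abundances and the length-by-class
panel use 1/n-weighted values, consistent with the counting rule.
"""

from __future__ import annotations

import base64
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .alignment import ReadAlignmentSet
from .annotation import TIER_LABELS, AnnotationResult


class InternalConsistencyError(RuntimeError):
    """Stage tallies disagree — indicates a pipeline bug, not bad input."""


@dataclass
class FunnelCounts:
    """Read counts surviving each pipeline stage of one library."""

    raw_reads: int = 0
    trimmed_reads: int = 0  # non-empty after adapter trimming
    size_filtered: int = 0  # within the length window
    rrna_removed: int = 0
    mapped: int = 0
    unmapped: int = 0
    suppressed: int = 0  # multimapper cap exceeded


@dataclass
class LibrarySummary:
    sample_id: str
    raw_reads: int
    trimmed_reads: int
    size_filtered: int
    rrna_removed: int
    mapped: int
    unmapped: int
    suppressed: int
    unannotated: int
    length_histogram: dict[tuple[int, str], int] = field(default_factory=dict)
    class_weights: dict[str, float] = field(default_factory=dict)
    length_by_class: dict[tuple[int, str], float] = field(default_factory=dict)

    @property
    def annotated_weight(self) -> float:
        return math.fsum(self.class_weights.values())

    def class_proportions(self) -> dict[str, float]:
        total = self.annotated_weight
        if total == 0:
            return {}
        return {c: w / total for c, w in self.class_weights.items()}


def summarize_library(
    sample_id: str,
    funnel: FunnelCounts,
    sets: Iterable[ReadAlignmentSet],
    annotation: AnnotationResult,
) -> LibrarySummary:
    """Assemble the per-library summary, cross-checking the stage tallies."""
    sets = list(sets)
    if not (funnel.raw_reads >= funnel.trimmed_reads >= funnel.size_filtered):
        raise InternalConsistencyError(
            f"{sample_id}: funnel not monotone "
            f"({funnel.raw_reads}, {funnel.trimmed_reads}, {funnel.size_filtered})"
        )
    entering_genome = funnel.size_filtered - funnel.rrna_removed
    if funnel.mapped + funnel.unmapped + funnel.suppressed != entering_genome:
        raise InternalConsistencyError(
            f"{sample_id}: mapped {funnel.mapped} + unmapped {funnel.unmapped} "
            f"+ suppressed {funnel.suppressed} != {entering_genome} entering reads"
        )
    if len(sets) != funnel.mapped:
        raise InternalConsistencyError(
            f"{sample_id}: {len(sets)} alignment sets but mapped count {funnel.mapped}"
        )

    length_histogram: dict[tuple[int, str], int] = {}
    for aset in sets:
        key = (len(aset.read.sequence), "unique" if aset.n == 1 else "multi")
        length_histogram[key] = length_histogram.get(key, 0) + 1

    length_by_class: dict[tuple[int, str], float] = {}
    for record in annotation.annotated:
        key = (len(record.alignment), record.class_label)
        length_by_class[key] = length_by_class.get(key, 0.0) + record.weight

    return LibrarySummary(
        sample_id=sample_id,
        raw_reads=funnel.raw_reads,
        trimmed_reads=funnel.trimmed_reads,
        size_filtered=funnel.size_filtered,
        rrna_removed=funnel.rrna_removed,
        mapped=funnel.mapped,
        unmapped=funnel.unmapped,
        suppressed=funnel.suppressed,
        unannotated=annotation.unannotated_alignments,
        length_histogram=length_histogram,
        class_weights=dict(annotation.class_weights),
        length_by_class=length_by_class,
    )


_FUNNEL_FIELDS = (
    "raw_reads", "trimmed_reads", "size_filtered", "rrna_removed",
    "mapped", "unmapped", "suppressed", "unannotated",
)

_CLASS_COLORS = dict(zip(TIER_LABELS, plt.get_cmap("tab10").colors))


def summary_to_dict(summary: LibrarySummary) -> dict:
    """JSON-serialisable twin of everything the HTML report shows."""
    lengths = sorted({k[0] for k in summary.length_histogram})
    return {
        "sample_id": summary.sample_id,
        "funnel": {f: getattr(summary, f) for f in _FUNNEL_FIELDS},
        "length_histogram": {
            str(length): {
                "unique": summary.length_histogram.get((length, "unique"), 0),
                "multi": summary.length_histogram.get((length, "multi"), 0),
            }
            for length in lengths
        },
        "class_weights": {c: summary.class_weights.get(c, 0.0) for c in TIER_LABELS},
        "class_proportions": summary.class_proportions(),
        "length_by_class": {
            str(length): {
                c: summary.length_by_class.get((length, c), 0.0)
                for c in TIER_LABELS
                if (length, c) in summary.length_by_class
            }
            for length in sorted({k[0] for k in summary.length_by_class})
        },
        "annotated_weight": summary.annotated_weight,
    }


def _fig_to_data_uri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="svg", bbox_inches="tight")
    plt.close(fig)
    payload = base64.b64encode(buf.getvalue()).decode("ascii")
    return f"data:image/svg+xml;base64,{payload}"


def _length_chart(summary: LibrarySummary) -> str:
    lengths = sorted({k[0] for k in summary.length_histogram}) or [0]
    unique = [summary.length_histogram.get((l, "unique"), 0) for l in lengths]
    multi = [summary.length_histogram.get((l, "multi"), 0) for l in lengths]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(lengths, unique, label="unique (n=1)", color="#4878cf")
    ax.bar(lengths, multi, bottom=unique, label="multimapper (n>1)", color="#d65f5f")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("reads")
    ax.set_title(f"{summary.sample_id}: mapped read lengths")
    ax.legend(fontsize=8)
    return _fig_to_data_uri(fig)


def _class_chart(summary: LibrarySummary) -> str:
    classes = [c for c in TIER_LABELS if summary.class_weights.get(c, 0.0) > 0]
    weights = [summary.class_weights[c] for c in classes]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(range(len(classes)), weights,
           color=[_CLASS_COLORS[c] for c in classes])
    ax.set_xticks(range(len(classes)))
    ax.set_xticklabels(classes, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("weighted abundance")
    ax.set_title(f"{summary.sample_id}: sRNA class abundance")
    return _fig_to_data_uri(fig)


def _length_by_class_chart(summary: LibrarySummary) -> str:
    lengths = sorted({k[0] for k in summary.length_by_class}) or [0]
    fig, ax = plt.subplots(figsize=(5, 3))
    bottom = [0.0] * len(lengths)
    for c in TIER_LABELS:
        values = [summary.length_by_class.get((l, c), 0.0) for l in lengths]
        if not any(values):
            continue
        ax.bar(lengths, values, bottom=bottom, label=c, color=_CLASS_COLORS[c])
        bottom = [b + v for b, v in zip(bottom, values)]
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("weighted abundance")
    ax.set_title(f"{summary.sample_id}: class by read length")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=7)
    return _fig_to_data_uri(fig)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>small RNA library report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 1em; }}
td, th {{ border: 1px solid #999; padding: 4px 10px; text-align: right; }}
th {{ background: #eee; }}
.sample {{ margin-bottom: 3em; }}
img {{ max-width: 520px; margin-right: 1em; }}
</style></head>
<body>
<h1>Small RNA library report</h1>
{sections}
</body></html>
"""

_SECTION = """<div class="sample" id="{sample_id}">
<h2>{sample_id}</h2>
<table>
<tr>{header_cells}</tr>
<tr>{value_cells}</tr>
</table>
<img alt="length histogram" src="{length_chart}">
<img alt="class abundance" src="{class_chart}">
<img alt="length by class" src="{length_class_chart}">
</div>
"""


def render_report(summaries: list[LibrarySummary], out_dir: str | Path) -> dict[str, Path]:
    """Write ``report.html`` and its JSON twin ``report.json``.

    The HTML is self-contained (charts are embedded SVG data URIs); the JSON
    holds every number shown, keyed by sample id.
    """
    if not summaries:
        raise ValueError("at least one library summary is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sections = []
    payload = {}
    for summary in summaries:
        payload[summary.sample_id] = summary_to_dict(summary)
        sections.append(
            _SECTION.format(
                sample_id=summary.sample_id,
                header_cells="".join(f"<th>{f}</th>" for f in _FUNNEL_FIELDS),
                value_cells="".join(
                    f"<td>{getattr(summary, f)}</td>" for f in _FUNNEL_FIELDS
                ),
                length_chart=_length_chart(summary),
                class_chart=_class_chart(summary),
                length_class_chart=_length_by_class_chart(summary),
            )
        )

    html_path = out_dir / "report.html"
    json_path = out_dir / "report.json"
    html_path.write_text(_PAGE.format(sections="\n".join(sections)))
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"html": html_path, "json": json_path}


def write_mapping_log(summaries: list[LibrarySummary], path: str | Path) -> None:
    """Funnel table as TSV: one row per sample."""
    with open(path, "wt") as fh:
        fh.write("sample_id\t" + "\t".join(_FUNNEL_FIELDS) + "\n")
        for s in summaries:
            fh.write(s.sample_id + "\t" + "\t".join(str(getattr(s, f)) for f in _FUNNEL_FIELDS) + "\n")
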
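"""Aggregation of annotated alignments into DE-ready weighted count tables.

Counts are 1/n-weighted: a read with n retained placements contributes 1/n
per placement, so a fully annotated read contributes exactly 1 regardless of
its multimapping status, and no read is double-counted. Fractional values
are the canonical representation; rounding to integers is an export option
for count-based statistics packages.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation import AnnotatedAlignment

DEFAULT_MIN_TOTAL = 20


class CountTable:
    """(feature_id, class) x sample matrix of weighted abundances.

    Thin wrapper over a pandas DataFrame whose row index is the MultiIndex
    (feature_id, class_label) and whose columns are sample ids.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.nlevels != 2:
            raise ValueError("count table rows must be keyed by (feature_id, class)")
        if frame.index.duplicated().any():
            raise ValueError("duplicate (feature_id, class) row keys")
        frame = frame.copy()
        frame.index.names = ["feature_id", "class_label"]
        self.frame = frame

    @classmethod
    def empty(cls, sample_ids: Iterable[str] = ()) -> "CountTable":
        idx = pd.MultiIndex.from_arrays([[], []], names=["feature_id", "class_label"])
        return cls(pd.DataFrame(index=idx, columns=list(sample_ids), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    def column_sums(self) -> dict[str, float]:
        return {s: math.fsum(self.frame[s].to_numpy()) for s in self.sample_ids}

    def row_sums(self) -> pd.Series:
        return self.frame.sum(axis=1)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.frame.equals(other.frame)


def accumulate_counts(
    annotated: Iterable[AnnotatedAlignment],
    sample_id: str,
) -> CountTable:
    """Sum 1/n weights per (feature, class) into one sample column.

    Per-feature sums use compensated (exact fsum) accumulation so the column
    total reproduces the library's emitted weight to well under 1e-9.
    """
    weights: dict[tuple[str, str], list[float]] = {}
    for record in annotated:
        weights.setdefault((record.feature_id, record.class_label), []).append(
            record.weight
        )
    if not weights:
        return CountTable.empty([sample_id])
    idx = pd.MultiIndex.from_tuples(
        sorted(weights), names=["feature_id", "class_label"]
    )
    values = [math.fsum(weights[key]) for key in sorted(weights)]
    return CountTable(pd.DataFrame({sample_id: values}, index=idx))


def merge_samples(tables: list[CountTable]) -> CountTable:
    """Outer-join single-sample tables; features absent from a sample are 0."""
    if not tables:
        return CountTable.empty()
    seen: set[str] = set()
    for table in tables:
        for sample in table.sample_ids:
            if sample in seen:
                raise ValueError(f"duplicate sample id {sample!r}")
            seen.add(sample)
    merged = pd.concat([t.frame for t in tables], axis=1).fillna(0.0)
    merged = merged.sort_index()
    return CountTable(merged)


def filter_low_abundance(table: CountTable, min_total: float = DEFAULT_MIN_TOTAL) -> CountTable:
    """Drop rows whose across-sample sum is below ``min_total``.

    Removing species with fewer than 20 counts summed over all libraries is
    the conventional pre-filter before differential-expression modeling; it
    is idempotent and a ``min_total`` of 0 is the identity.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.row_sums() >= min_total
    return CountTable(table.frame.loc[keep])


def write_counts(table: CountTable, path: str | Path, rounding: str = "none") -> None:
    from .sequence_io import write_counts_tsv

    write_counts_tsv(table, path, rounding=rounding)
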
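import json
import math

import numpy as np
import pandas as pd
import pytest

from srnapipe.annotation import AnnotatedAlignment
from srnapipe.quantify import (
    CountTable,
    accumulate_counts,
    filter_low_abundance,
    merge_samples,
)
from srnapipe.report import (
    FunnelCounts,
    InternalConsistencyError,
    LibrarySummary,
    render_report,
    summarize_library,
    write_mapping_log,
)
from srnapipe.sequence_io import AlignmentRecord


def _annotated(feature_id, class_label, weight, read_id="r", length=22, start=0):
    aln = AlignmentRecord(read_id, "chr1", start, start + length, "+", 0, "A" * length)
    return AnnotatedAlignment(aln, class_label, feature_id, weight)


def _table(rows, samples):
    idx = pd.MultiIndex.from_tuples(
        [r[0] for r in rows], names=["feature_id", "class_label"]
    )
    return CountTable(pd.DataFrame([r[1] for r in rows], index=idx, columns=samples))


class TestAccumulateCounts:
    def test_multimapper_on_one_te_sums_to_one(self):
        records = [
            _annotated("L1-x", "TE_sense", 0.25, read_id="r1", start=i * 500)
            for i in range(4)
        ]
        table = accumulate_counts(records, "s1")
        assert len(table) == 1
        assert table.frame.loc[("L1-x", "TE_sense"), "s1"] == 1.0

    def test_empty_stream_gives_empty_column(self):
        table = accumulate_counts([], "s1")
        assert len(table) == 0 and table.sample_ids == ["s1"]

    def test_column_sum_equals_read_count_when_fully_annotated(self):
        records = [_annotated("a", "miRNA", 1.0)]
        records += [_annotated("b", "exon", 0.5, start=i) for i in range(2)]
        records += [_annotated("c", "TE_sense", 0.25, start=i) for i in range(4)]
        table = accumulate_counts(records, "s1")
        assert table.column_sums()["s1"] == pytest.approx(3.0, abs=1e-12)

    def test_column_sum_tracks_emitted_weight_with_awkward_n(self):
        # weights 1/3 and 1/7 are inexact in binary; compensated summation
        # must still reproduce the emitted total to 1e-9
        records = [_annotated("x", "intron", 1 / 3, read_id=f"r{i}", start=i)
                   for i in range(3000)]
        records += [_annotated("y", "exon", 1 / 7, read_id=f"q{i}", start=i)
                    for i in range(7000)]
        table = accumulate_counts(records, "s1")
        emitted = math.fsum(r.weight for r in records)
        assert abs(table.column_sums()["s1"] - emitted) < 1e-9


class TestMergeSamples:
    def test_disjoint_tables_fill_zeros(self):
        t1 = _table([(("a", "miRNA"), [1.0])], ["s1"])
        t2 = _table([(("b", "exon"), [2.0])], ["s2"])
        merged = merge_samples([t1, t2])
        assert merged.frame.shape == (2, 2)
        assert merged.frame.loc[("a", "miRNA"), "s2"] == 0.0
        assert merged.frame.loc[("b", "exon"), "s1"] == 0.0

    def test_same_table_under_two_ids_gives_identical_columns(self):
        t1 = _table([(("a", "miRNA"), [1.5]), (("b", "exon"), [0.25])], ["s1"])
        t2 = CountTable(t1.frame.rename(columns={"s1": "s2"}))
        merged = merge_samples([t1, t2])
        assert (merged.frame["s1"] == merged.frame["s2"]).all()

    def test_duplicate_sample_id_rejected(self):
        t = _table([(("a", "miRNA"), [1.0])], ["s1"])
        with pytest.raises(ValueError, match="duplicate"):
            merge_samples([t, t])

    def test_column_sums_preserved(self):
        rng = np.random.default_rng(43)
        tables = []
        for s in range(3):
            rows = [
                ((f"f{rng.integers(20)}", "exon"), [float(rng.random())])
                for _ in range(10)
            ]
            # de-duplicate row keys
            seen = {}
            for key, val in rows:
                seen[key] = [seen.get(key, [0.0])[0] + val[0]]
            tables.append(_table(sorted(seen.items()), [f"s{s}"]))
        before = {s: t.column_sums()[s] for t in tables for s in t.sample_ids}
        after = merge_samples(tables).column_sums()
        for sample, total in before.items():
            assert after[sample] == pytest.approx(total, abs=1e-12)


class TestFilterLowAbundance:
    def test_default_threshold_drops_only_sub_20_rows(self):
        table = _table(
            [(("a", "miRNA"), [6.5, 6.5]), (("b", "exon"), [10.0, 10.0]),
             (("c", "TE_sense"), [100.0, 150.0])],
            ["s1", "s2"],
        )
        kept = filter_low_abundance(table, 20)
        assert set(kept.frame.index.get_level_values(0)) == {"b", "c"}

    def test_zero_threshold_is_identity(self):
        table = _table([(("a", "miRNA"), [0.5])], ["s1"])
        assert filter_low_abundance(table, 0) == table

    def test_idempotent_and_recount(self):
        rng = np.random.default_rng(47)
        rows = [((f"f{i}", "exon"), [float(rng.uniform(0, 40))]) for i in range(100)]
        table = _table(rows, ["s1"])
        once = filter_low_abundance(table, 20)
        twice = filter_low_abundance(once, 20)
        assert once == twice
        assert (once.row_sums() >= 20).all()
        dropped = len(table) - len(once)
        assert dropped + len(once) == 100


class TestSummarizeLibrary:
    def test_zero_read_library(self):
        from srnapipe.annotation import AnnotationResult

        summary = summarize_library(
            "s0", FunnelCounts(), [], AnnotationResult([], {}, 0)
        )
        assert summary.raw_reads == 0 and summary.annotated_weight == 0.0
        assert summary.class_proportions() == {}

    def test_funnel_and_class_weights_consistent(self, toy_ref, genome_index, annotation_db):
        from srnapipe.alignment import select_genome_alignments
        from srnapipe.annotation import annotate_library
        from srnapipe.sequence_io import SmallRead

        mir = next(f for f in toy_ref.features["miRNA"] if f.feature_id == "mir-1")
        seq = toy_ref.genome[mir.chrom][mir.start : mir.end]
        sets = []
        funnel = FunnelCounts(raw_reads=10, trimmed_reads=10, size_filtered=10,
                              rrna_removed=3, mapped=6, unmapped=0, suppressed=1)
        for i in range(6):
            aset, status = select_genome_alignments(SmallRead(f"r{i}", seq), genome_index)
            assert status == "mapped"
            sets.append(aset)
        result = annotate_library(sets, annotation_db)
        summary = summarize_library("s1", funnel, sets, result)
        assert summary.mapped == 6 and summary.rrna_removed == 3
        assert summary.annotated_weight == pytest.approx(6.0)
        assert sum(summary.class_proportions().values()) == pytest.approx(1.0)
        assert sum(summary.length_histogram.values()) == summary.mapped

    def test_inconsistent_tallies_raise(self):
        from srnapipe.annotation import AnnotationResult

        funnel = FunnelCounts(raw_reads=5, trimmed_reads=5, size_filtered=5,
                              rrna_removed=0, mapped=3, unmapped=0, suppressed=0)
        with pytest.raises(InternalConsistencyError):
            summarize_library("s1", funnel, [], AnnotationResult([], {}, 0))


def _summary(sample_id="s1"):
    return LibrarySummary(
        sample_id=sample_id, raw_reads=10, trimmed_reads=10, size_filtered=9,
        rrna_removed=1, mapped=8, unmapped=0, suppressed=0, unannotated=1,
        length_histogram={(22, "unique"): 6, (22, "multi"): 1, (24, "unique"): 1},
        class_weights={"miRNA": 5.0, "TE_sense": 2.5},
        length_by_class={(22, "miRNA"): 5.0, (22, "TE_sense"): 1.5, (24, "TE_sense"): 1.0},
    )


class TestRenderReport:
    def test_html_and_json_twins_agree(self, tmp_path):
        summary = _summary()
        paths = render_report([summary], tmp_path)
        assert paths["html"].exists()
        payload = json.loads(paths["json"].read_text())
        twin = payload["s1"]
        assert twin["funnel"]["mapped"] == 8
        assert twin["class_weights"]["miRNA"] == 5.0
        assert twin["annotated_weight"] == pytest.approx(7.5)
        # every funnel number shown in the HTML table exists in the page
        html = paths["html"].read_text()
        for value in twin["funnel"].values():
            assert f"<td>{value}</td>" in html

    def test_two_samples_both_present(self, tmp_path):
        paths = render_report([_summary("s1"), _summary("s2")], tmp_path)
        payload = json.loads(paths["json"].read_text())
        assert set(payload) == {"s1", "s2"}
        html = paths["html"].read_text()
        assert 'id="s1"' in html and 'id="s2"' in html

    def test_length_histogram_totals_match_mapped(self, tmp_path):
        summary = _summary()
        paths = render_report([summary], tmp_path)
        payload = json.loads(paths["json"].read_text())
        total = sum(
            bucket["unique"] + bucket["multi"]
            for bucket in payload["s1"]["length_histogram"].values()
        )
        assert total == payload["s1"]["funnel"]["mapped"]

    def test_html_is_self_contained(self, tmp_path):
        paths = render_report([_summary()], tmp_path)
        html = paths["html"].read_text()
        assert "http://" not in html and "https://" not in html
        assert "data:image/svg+xml" in html

    def test_requires_at_least_one_summary(self, tmp_path):
        with pytest.raises(ValueError):
            render_report([], tmp_path)


def test_mapping_log_funnel_rows(tmp_path):
    path = tmp_path / "mapping_log.tsv"
    write_mapping_log([_summary("s1"), _summary("s2")], path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("sample_id\traw_reads")
    assert len(lines) == 3
    assert lines[1].split("\t")[0] == "s1"
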
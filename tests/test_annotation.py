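import numpy as np
import pytest

from oracles import brute_force_classify
from srnapipe.alignment import ReadAlignmentSet
from srnapipe.annotation import (
    DEFAULT_ORDER,
    AnnotationDB,
    PriorityOrder,
    annotate_library,
    build_annotation_db,
    classify_alignment,
)
from srnapipe.sequence_io import AlignmentRecord, FeatureInterval, SmallRead


def _aln(chrom="chr1", start=0, length=22, strand="+", read_id="r"):
    return AlignmentRecord(read_id, chrom, start, start + length, strand, 0, "A" * length)


def _db(features, order=None):
    db = AnnotationDB(order=order)
    by_class = {}
    for f in features:
        by_class.setdefault(f.class_label, []).append(f)
    for class_label, ivs in by_class.items():
        db.add_intervals(class_label, ivs)
    return db


class TestPriorityOrder:
    def test_default_order(self):
        assert PriorityOrder().tiers == DEFAULT_ORDER

    def test_duplicate_and_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            PriorityOrder(["miRNA", "miRNA"])
        with pytest.raises(ValueError):
            PriorityOrder(["miRNA", "tRNA"])

    def test_te_sense_must_precede_antisense(self):
        with pytest.raises(ValueError):
            PriorityOrder(["TE_antisense", "TE_sense"])

    def test_from_string(self):
        order = PriorityOrder.from_string("miRNA,intron")
        assert order.tiers == ["miRNA", "intron"]


class TestClassifyAlignment:
    def _nested_features(self):
        return [
            FeatureInterval("my-mir", "miRNA", "chr1", 100, 122, "+"),
            FeatureInterval("my-hairpin", "hairpin", "chr1", 90, 170, "+"),
            FeatureInterval("host-intron", "intron", "chr1", 0, 600, "+"),
        ]

    def test_intronic_mirna_wins_over_intron(self):
        db = _db(self._nested_features())
        result = classify_alignment(_aln(start=100, length=22), db)
        assert result == ("miRNA", "my-mir")

    def test_reversed_priority_flips_to_intron(self):
        order = PriorityOrder(["intron", "hairpin", "miRNA"])
        db = _db(self._nested_features(), order=order)
        result = classify_alignment(_aln(start=100, length=22), db)
        assert result == ("intron", "host-intron")

    def test_antisense_te_alignment(self):
        db = _db([FeatureInterval("L1-x", "TE", "chr1", 0, 300, "+")])
        assert classify_alignment(_aln(start=50, strand="-"), db) == ("TE_antisense", "L1-x")
        assert classify_alignment(_aln(start=50, strand="+"), db) == ("TE_sense", "L1-x")

    def test_no_overlap_returns_none(self):
        db = _db(self._nested_features())
        assert classify_alignment(_aln(chrom="chr2", start=100), db) is None

    def test_sense_strand_required_for_mirna(self):
        db = _db([FeatureInterval("m", "miRNA", "chr1", 100, 122, "+")])
        assert classify_alignment(_aln(start=100, strand="-"), db) is None

    def test_pirna_cluster_accepts_both_strands(self):
        db = _db([FeatureInterval("pi1", "piRNA_cluster", "chr1", 0, 1000, "+")])
        for strand in "+-":
            assert classify_alignment(_aln(start=300, strand=strand), db) == \
                ("piRNA_cluster", "pi1")

    def test_overlap_fraction_threshold(self):
        db = _db([FeatureInterval("e", "exon", "chr1", 100, 200, "+")])
        # 11 of 22 bases inside the exon: exactly half, passes >= 0.5
        assert classify_alignment(_aln(start=89, length=22), db) == ("exon", "e")
        # 10 of 22: below half
        assert classify_alignment(_aln(start=88, length=22), db) is None

    def test_largest_overlap_then_feature_id_tie_break(self):
        db = _db([
            FeatureInterval("b-exon", "exon", "chr1", 100, 200, "+"),
            FeatureInterval("a-exon", "exon", "chr1", 100, 200, "+"),
            FeatureInterval("c-exon", "exon", "chr1", 100, 115, "+"),
        ])
        # full overlap beats partial; a-exon vs b-exon resolved lexicographically
        assert classify_alignment(_aln(start=100, length=22), db) == ("exon", "a-exon")

    def test_matches_brute_force_on_random_fixtures(self, toy_ref, annotation_db):
        rng = np.random.default_rng(29)
        order = PriorityOrder()
        chroms = sorted(toy_ref.genome)
        for i in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(16, 33))
            start = int(rng.integers(0, len(toy_ref.genome[chrom]) - length))
            strand = "+-"[int(rng.integers(2))]
            aln = _aln(chrom=chrom, start=start, length=length, strand=strand)
            expected = brute_force_classify(aln, toy_ref.features, order, 0.5)
            assert classify_alignment(aln, annotation_db) == expected


class TestBuildAnnotationDb:
    def test_all_classes_loaded(self, bed_paths, toy_ref):
        db = build_annotation_db(bed_paths)
        for class_label in toy_ref.features:
            assert db.has_class(class_label)
            assert len(db.features(class_label)) == len(toy_ref.features[class_label])

    def test_missing_file_skips_tier_with_warning(self, bed_paths, caplog):
        paths = dict(bed_paths)
        del paths["piRNA_cluster"]
        with caplog.at_level("WARNING"):
            db = build_annotation_db(paths)
        assert not db.has_class("piRNA_cluster")
        assert any("piRNA_cluster" in r.message for r in caplog.records)

    def test_interval_queries_match_linear_scan(self, toy_ref, annotation_db):
        rng = np.random.default_rng(31)
        for _ in range(100):
            chrom = "chr1"
            start = int(rng.integers(0, 11000))
            end = start + 1000
            for class_label in toy_ref.features:
                got = {f.feature_id for f in annotation_db.query(class_label, chrom, start, end)}
                expected = {
                    f.feature_id
                    for f in toy_ref.features[class_label]
                    if f.chrom == chrom and f.start < end and f.end > start
                }
                assert got == expected


class TestAnnotateLibrary:
    def _set(self, read_id, alignments):
        read = SmallRead(read_id, alignments[0].sequence)
        return ReadAlignmentSet(read_id=read_id, read=read, alignments=alignments)

    def test_multimapper_split_across_te_loci(self):
        db = _db([
            FeatureInterval(f"L1-{i}", "TE", "chr1", i * 1000, i * 1000 + 300, "+")
            for i in range(4)
        ])
        alns = [_aln(start=i * 1000 + 10, read_id="r1") for i in range(4)]
        result = annotate_library([self._set("r1", alns)], db)
        assert len(result.annotated) == 4
        assert all(rec.weight == 0.25 for rec in result.annotated)
        assert result.class_weights == {"TE_sense": pytest.approx(1.0)}

    def test_unique_mirna_read_weight_one(self):
        db = _db([FeatureInterval("m", "miRNA", "chr1", 0, 22, "+")])
        result = annotate_library([self._set("r1", [_aln(start=0, read_id="r1")])], db)
        assert len(result.annotated) == 1
        assert result.annotated[0].weight == 1.0

    def test_partially_annotated_multimapper_emits_partial_weight(self):
        db = _db([FeatureInterval("e", "exon", "chr1", 0, 200, "+")])
        alns = [_aln(start=10, read_id="r1"), _aln(chrom="chr2", start=5000, read_id="r1")]
        result = annotate_library([self._set("r1", alns)], db)
        assert len(result.annotated) == 1
        assert result.annotated[0].weight == 0.5
        assert result.unannotated_alignments == 1

    def test_per_read_emitted_weight_never_exceeds_one(self, toy_ref, annotation_db, genome_index):
        from srnapipe.alignment import select_genome_alignments
        import math

        rng = np.random.default_rng(37)
        sets = []
        for i in range(50):
            chrom = "chr1" if i % 2 else "chr2"
            start = int(rng.integers(0, len(toy_ref.genome[chrom]) - 22))
            read = SmallRead(f"r{i}", toy_ref.genome[chrom][start : start + 22])
            aset, status = select_genome_alignments(read, genome_index)
            if status == "mapped":
                sets.append(aset)
        result = annotate_library(sets, annotation_db)
        per_read: dict[str, list[float]] = {}
        for rec in result.annotated:
            per_read.setdefault(rec.alignment.read_id, []).append(rec.weight)
        for read_id, weights in per_read.items():
            assert math.fsum(weights) <= 1 + 1e-12
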
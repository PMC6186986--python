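# Methods

## Scope and model

`srnapipe` treats a single-end small RNA-seq library as a mixture of short
(16–36 nt) RNA species whose genomic origin — structural RNA, mature miRNA,
hairpin precursor, exon, sense/antisense transposable element (TE), intron,
or piRNA cluster — is decided per alignment by a priority decision tree,
and whose abundance is quantified with 1/n multimapper weighting. The
pipeline is deterministic end to end: no stage uses randomness, so
identical inputs and configuration reproduce byte-identical outputs.

## Adapter trimming

A candidate adapter occurrence is a pair (p, L): adapter prefix of length
L ≥ `min_overlap` (default 3) aligned at read positions [p, p+L), either
reaching the read's 3′ end or, for L equal to the full adapter length,
internal to the read (read-through into downstream sequence). A candidate
is valid when its Hamming mismatches are ≤ ⌊`error_rate`·L⌋ (default rate
0.1). Among valid candidates the fewest mismatches wins; ties resolve to
the smallest p, i.e. the most aggressive trim. The tie-break direction is
deliberate: partially degraded adapter dimers are the dominant artifact in
small-RNA libraries, and an under-trimmed dimer pollutes downstream
classes, while an over-trimmed genuine insert merely falls below the length
filter. The default adapter is the TruSeq small-RNA 3′ adapter
(`TGGAATTCTCGGGTGCCAAGG`); only 3′ trimming is implemented, matching
single-end small-RNA chemistry. A read trimmed to length zero survives as
an empty read and is removed by the length filter.

## Size selection

Inclusive window 16–36 nt. Reads below/above are tallied separately so the
funnel identity `kept + below + above = input` is checkable.

## Alignment

Two regimes share one exhaustive ungapped aligner whose contract is
set-equality with a naive two-strand Hamming scan of every window:

* **rRNA filtering** — up to 2 mismatches, best hit only; a read is
  discarded iff any placement exists. Only the mapped/unmapped decision is
  used. The permissive threshold removes rRNA degradation products even in
  the presence of sequencing errors.
* **Genome alignment** — 0 mismatches, all placements on both strands.
  Reads with more than `max_loci` placements (default 100) are suppressed
  and tallied; reads with 1 ≤ n ≤ 100 are retained, and this n (fixed here,
  before annotation) defines the 1/n weight. The boundary is inclusive: a
  read with exactly 100 placements is retained.

Reverse-strand placements compare the read's reverse complement against
the forward reference; coordinates are always reported on the forward
strand, 0-based half-open. An `N` in a read mismatches every reference
base (and reference `N` matches nothing), so N-containing reads cannot map
at the zero-mismatch genome stage.

The implementation scans a sliding window view of each chromosome and
memoises results per (sequence, parameters) — small-RNA libraries are
highly redundant, so repeated sequences are aligned once. Any external
ungapped aligner can substitute via SAM ingest (`sam:` per sample); records
must have pure-match CIGARs, and the same cap semantics are applied to the
ingested alignment sets.

## Annotation decision tree

Default tier order: structural_RNA, miRNA, hairpin, exon, TE_sense,
TE_antisense, intron, piRNA_cluster; user-reorderable, with the single
constraint that TE_sense precedes TE_antisense (both tiers query the one
strand-annotated TE set). Mature miRNA ranks above hairpin so reads from
the precursor outside the mature annotation (loop/star fragments) are
labeled hairpin.

An alignment is claimed by the first tier containing a feature that
overlaps it by at least `min_overlap_frac` of the *alignment's* length
(default 0.5 — robust to boundary-spanning reads; exposed as a flag) and
passes the tier's strand rule:

| tier | rule |
|---|---|
| structural_RNA, miRNA, hairpin, exon, intron | alignment strand == feature strand |
| TE_sense | strands equal |
| TE_antisense | strands opposite |
| piRNA_cluster | either strand (clusters are frequently bidirectional) |

Requiring sense overlap for the mRNA-derived and miRNA tiers follows
small-RNA biogenesis; the TE split is the sense/antisense distinction
itself. Within a tier, the feature with the largest overlap wins, ties by
lexicographically smallest feature id — deterministic and independent of
annotation file order. Classification is per alignment, not per read: a
multimapper's placements may receive different classes. Unclassified
alignments are tallied, not emitted, so a partially annotated multimapper
contributes less than 1 total weight.

## Counting

The count for row (feature, class) and sample s is the sum of 1/n weights
of alignments assigned to it. Per-row and per-column totals use compensated
(`math.fsum`) summation, so the column total matches the library's emitted
annotated weight to well below the 1e-9 documented tolerance even with
inexact weights like 1/3. Fractional counts are canonical; the TSV export
offers nearest-integer rounding for statistics packages that require
integer counts. Rows are sorted by (class, feature) for deterministic
files. The optional low-abundance pre-filter drops rows whose across-sample
sum is below 20 (configurable), the conventional sensitivity filter before
differential-expression modeling; it is idempotent.

## Report

`report.html` is fully self-contained (matplotlib SVG charts embedded as
data URIs, no network assets); `report.json` is its machine-readable twin
containing every plotted number, which is what the tests assert against.
Conventions: the read-length histogram counts each mapped read once, split
by unique (n = 1) vs multimapper (n > 1); class abundances and the
length-by-class panel use 1/n-weighted values, consistent with counting.
`mapping_log.tsv` holds the per-stage funnel, which satisfies
`mapped + unmapped + suppressed = size-selected − rRNA-removed` exactly
(violations raise an internal-consistency error rather than producing a
silently wrong report).

## Synthetic data generator

`fixtures.generate_toy_reference(seed)` builds a ~35 kb two-chromosome
genome by concatenating random filler with planted features: unique
structural RNAs, miRNA/hairpin pairs (mature inside the precursor), exons,
strand-mixed TEs, introns, piRNA clusters; a mature miRNA nested in a
hairpin nested in an intron (the case the priority tree exists for); and
exact-copy repeat families of 100 and 150 copies straddling the multimapper
cap. Three random decoy "rRNA" sequences form the contaminant reference.
All features are non-overlapping by construction except the deliberate
nesting, and unique-locus feature sequences are independent random draws,
so at these lengths chance duplicate placements are vanishingly rare.

`fixtures.simulate_reads` draws reads by class mix (defaults: miRNA 25 %,
TE sense/antisense 15 %/10 %, exon 12 %, structural RNA / intron /
piRNA 8 % each, hairpin 7 %, rRNA 4 %, plus 1 % each of unmappable decoys
and reads from the two repeat families — loosely shaped like a real
miRNA-dominated library). Inserts are 18–30 nt with a mode at 22 nt,
sampled from per-class regions chosen to be unambiguous (hairpin reads
outside the mature miRNA, intron reads outside the nested hairpin); the
full 3′ adapter is appended. Class counts are apportioned by largest
remainder, so fractions are exact. Reads are sequencing-error-free by
default; an optional substitution count exists for rRNA decoys only, to
exercise the filter's mismatch tolerance (at the zero-mismatch genome
stage an error would simply unmap the read, so no genome error model is
useful). The reference and the read simulator use independent PRNG streams
(distinct spawn keys), so the same integer seed may safely be used for
both.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: base-quality error profiles, ligation bias,
expression-level dispersion across features, isomiR end heterogeneity,
overlapping/ambiguous annotation (other than the planted nesting), and
genome-scale repeat complexity. Tests on this fixture validate the
pipeline's *semantics* (trimming rules, exhaustiveness, priority, strand
rules, weighting, conservation, determinism), not classification accuracy
on any real genome.

## Problem sizes and numerical choices

The toy genome is kept near 35 kb and test libraries at 1,500–10,000 reads;
the bundled verification script uses 10,000 reads, which is ample to
exercise every class and both repeat families while keeping runs
interactive. Tolerances: count conservation 1e-9 (achieved exactly via
compensated summation in practice); TSV round-trip 1e-6 (fixed 6-decimal
export). Tie-breaks everywhere are lexicographic after the primary
criterion, making every output independent of input iteration order.

## Known limitations

* Ungapped alignment only — no spliced or indel-tolerant mapping; reads
  crossing splice junctions are lost at the genome stage.
* The in-memory exhaustive aligner targets toy-to-small references; for a
  mammalian genome, use an external ungapped aligner and the SAM ingest
  path (same cap and weighting semantics apply).
* Single-end reads only; no UMI handling, quality trimming, or adapter
  auto-detection.
* n is fixed at alignment selection: an alignment suppressed later by
  annotation does not renormalise its siblings' weights.
* piRNA ping-pong signature analysis, novel-miRNA discovery and tRF
  sub-typing are out of scope; downstream differential testing is left to
  dedicated statistics packages consuming `counts.tsv`.
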
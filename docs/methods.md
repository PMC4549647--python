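# Methods

This note records the models, rules, numerical conventions and design
choices behind `regumap`, and what the synthetic data can and cannot
show about real data.

## Genic-location classification

Variants are 1-based points; gene models are 1-based inclusive intervals
(GFF3 convention); peak tracks are 0-based half-open (BED convention).
The single conversion between the two worlds is `regumap.io.to_zero_based`:
a variant at position p overlaps a BED interval [s, e) iff s ≤ p−1 < e.

Each variant receives exactly one class. Within a gene the precedence is
CDS > UTR > splice donor > intron; a variant inside any transcript beats
flanking calls; among several candidate genes the smallest distance wins,
with lexicographic gene id as the deterministic tie-break. Flanking calls
(upstream/downstream) are strand-aware within `flank_bp` of the
transcript boundaries, and a variant farther than `flank_bp` from every
transcript is intergenic. `flank_bp` defaults to 10 kb, matching the
usual "intergenic = more than 10 kb from a gene" convention; the
flanking window itself is rarely stated explicitly in annotation
pipelines, so we use the same 10 kb on both sides and expose it as a
parameter.

Missense status is decided by direct codon translation (standard table,
via Biopython): the variant's offset in the coding sequence locates its
codon, the alternate allele (reverse-complemented for minus-strand genes)
is substituted, and the call is "missense" iff the amino acid changes and
neither side is a stop — stop gains/losses are deliberately excluded.
The splice-donor class is purely positional: the first two intronic bases
3′ of an exon in transcription direction. Acceptor sites are not
modelled, and transcript-level consequences that require isoform logic
(e.g. nonsense-mediated-decay targeting) are never computed — they are
accepted as pass-through flags on the input and reported as such.

## LD model and proxy expansion

r² between two sites is computed from phased haplotype counts,
D²/(p_A p_a p_B p_b), which equals the squared Pearson correlation of
the 0/1 columns; tests verify agreement with an independent
`numpy.corrcoef` oracle to 1e-12 and exact symmetry. Proxy expansion
keeps every panel site with r² ≥ `r2_min` (default 0.80) within
`max_dist_bp` (default 200 kb, wide enough to span enhancer domains) of
a seed, excluding the seed's own column: proxies are by definition new
variants relative to the seed panel. Using phased haplotypes rather than
EM estimation from genotypes matches reference-panel-style input and
removes estimation ambiguity. Distances are position differences, not
interval arithmetic.

The synthetic panel controls r² by founder copying: the two founders of
an LD block carry complementary alleles everywhere, each haplotype picks
a founder per block, and each (haplotype, site) allele flips with
probability f. Every column is then a noisy copy of the same
Bernoulli(1/2) indicator, giving corr(X_s, X_t) = (1−2f)² for same-block
sites and hence E[r²] ≈ (1−2f)⁴, exactly 1 at f = 0, and independence
across blocks. Monomorphic columns (rare, small panels) are dropped, not
resampled — resampling would silently distort the block structure. This
model ignores recombination maps, demography and realistic allele
frequency spectra on purpose: it tunes the one quantity the expansion
consumes.

## Regulatory rules

Per scope: promoter ⇐ PolII; enhancer ⇐ (H3K27Ac ∨ H3K36me3 ∨ H3K27me3)
∧ ¬PolII; insulator ⇐ CTCF; dnase ⇐ DNase; eqtl ⇐ eQTL-table membership
for the scope. The repressive mark H3K27me3 is kept in the default
enhancer list because the operational definition this package implements
includes it verbatim; `enhancer_marks` makes the list configurable for
users who prefer an activating-marks-only rule. The mark vocabulary is a
closed enum (catching manifest typos that would silently disable a
rule); transcription-factor tracks are declared with `kind: tf` and feed
only pass-through `tf_hits`.

Multi-cell scope is the union of all cells' tracks per mark. For
promoter/insulator/dnase/eqtl this is equivalent to OR-ing per-cell
calls; for the enhancer flag it is not — the absence-of-PolII clause is
evaluated against the union, so a histone mark in one cell plus PolII in
another yields no multi-cell enhancer call even though one per-cell call
is positive. This asymmetry is inherent to the rule, and the union
semantics is the one used for multi-cell summaries.

`primary_motif` (promoter > enhancer > insulator > none) is a display
convenience only; a variant can be, say, an insulator with open
chromatin. The summary's `no_flag` row counts variants with all five
flags false, while `coverage` counts variants with any regulatory
evidence including TF-binding-only hits — TF binding is part of the
requested annotation set, so a variant whose only evidence is a TF peak
contributes to coverage but still counts as motif-unflagged. With the
packaged worked example this yields 5/72 unflagged and 94.4% coverage
from one consistent assignment.

## Enrichment statistics

Fold = (k/n)/rate. The binomial p-value is the exact upper tail
P(X ≥ k | n, rate); the permutation alternative resamples size-n
background sets (add-one smoothing) and agrees with the binomial within
Monte-Carlo error when the background is a rate. The 95% interval on
fold is Clopper–Pearson on k/n divided by the rate; a zero background
rate with overlapping query is an error (infinite fold), and k = 0 gives
fold 0 with p 1.

The Yates-corrected chi-square is implemented directly:
X² = Σ max(|O−E|−0.5, 0)²/E, df 1, with the correction clamped at zero
when |O−E| < 0.5 — the standard convention, which guarantees
X²_Yates ≤ X²_Pearson on every table (scipy's implementation shifts O by
0.5 without clamping, so the two agree exactly only where |O−E| ≥ 0.5;
tests compare them on that region). A zero margin raises; expected
counts below 5 warn, and Fisher's exact test is provided as the
small-count fallback. Correction is always applied to 2×2 tables. Raw
p-values are reported by default; Benjamini–Hochberg q-values are
available behind `adjust=True` for the many-test cross-cell report.

Deficit tests against a known expected rate report the exact binomial
lower tail P(X ≤ k | n, rate) as the primary p-value, with the exact
two-sided p and a 1-df chi-square goodness of fit as alternatives.

## Planted-enrichment simulation

`gen_peak_tracks` drops uniform background intervals of width w so that
the expected covered fraction equals `background_peak_fraction` — the
interval count solves 1 − (1 − w/L)^n = f, compensating for
self-overlap among random intervals. In the designated cell's designated
marks, background peaks overlapping a target variant are removed and
each target is covered by a planted peak with probability
min(1, planted_fold × f), so the true fold at targets is exactly the
planted factor (capped at certainty, with a logged warning when the
product exceeds 1) and target coverage in every other cell stays at
background. Under the null (fold 1) the planted cell and the others are
exchangeable at the targets, which the type-I simulation exploits: at
α = 0.05 the corrected test rejects in ≈2% of null replicates
(conservative, as expected).

Recovery checks run under the worked example's study conditions — three
cell types with the seven-histone-mark panel, 500 targets, 2% background.
The per-replicate fold estimate pools the planted cell's marks (the
pooled estimator's sampling error at fold 2 is ≈0.17, comfortably within
±20%, whereas a single-mark estimate would not be), and detection means
at least one planted mark's planted-vs-reference comparison is
significant at 5%.

Problem sizes throughout (500 targets, 50 recovery replicates, 1000 null
replicates, 1 Mb contig) were chosen as the smallest at which the
binomial noise terms above are clearly separated from the tolerances
being checked.

## What the synthetic data does not show

The generators emulate block LD, transcript structure and peak coverage,
not real genomes: there is one synthetic contig (nothing in the method
is inter-chromosomal), no recombination hotspots, no frequency spectrum,
no peak-width or GC structure, and the worked example's coordinates are
invented — only its per-class counts are meaningful. Passing tests
therefore demonstrate that the algorithms are correct and calibrated
under controlled conditions, not that any particular real variant panel
has these properties. Numbers that depend on live external resources
(reference-panel proxy counts, database-specific fold values) are out of
scope by design; the LD and enrichment modules are validated by the
synthetic recovery and property suites instead.

## Degenerate inputs and tie-breaks

Unknown contigs raise for gene lookups and are configurable
(false-with-warning by default) for track overlaps; duplicate variant
ids, unsorted/overlapping gene intervals, BED intervals with end ≤
start, duplicate eQTL triples, monomorphic panel columns and panels with
fewer than four haplotypes are all rejected at load/construction time.
Equal-distance gene candidates break ties lexicographically; equal
overlap counts in a cross-cell pair short-circuit to statistic 0, p 1
(covering the all-zero margin case); report percentages are rounded to
one decimal.
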
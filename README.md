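# regumap

Most risk variants found for complex autoimmune diseases fall outside
protein-coding sequence, so the question "what does this variant do?"
usually becomes "which regulatory element does it sit in, and in which
cell type is that element active?". `regumap` answers that question
locally and reproducibly for a panel of risk variants: it classifies each
variant's genic location, expands the panel to linkage-disequilibrium
proxies from phased haplotypes, calls promoter / enhancer / insulator /
open-chromatin / eQTL status from chromatin peak tracks, and quantifies
cell-type specificity with enrichment statistics. It is aimed at
geneticists and computational biologists who want a transparent,
scriptable version of the proxy-search-plus-annotation workflow, with a
synthetic-data module so every stage is testable without downloads.

## The statistics at the core

**LD proxies.** For biallelic sites A and B with phased haplotype
frequencies, r² = D² / (p_A p_a p_B p_b) with D = p_AB − p_A·p_B — the
squared Pearson correlation of the 0/1 allele columns. A proxy set for a
seed variant is every panel site with r² ≥ 0.80 within 200 kb, a window
wide enough to cover enhancer elements.

**Regulatory rules.** Per scope (one cell type, or the multi-cell union
of tracks): promoter ⇐ Pol II occupancy; enhancer ⇐ H3K27Ac, H3K36me3
and/or H3K27me3 occupancy in the absence of Pol II; insulator ⇐ CTCF;
plus DNase-peak and eQTL flags. A variant may carry several flags.

**Enrichment.** Fold = (k/n) / background rate for k of n variants
overlapping a track, with an exact one-sided binomial (or permutation)
p-value and a Clopper–Pearson interval. Cross-cell comparisons use the
2×2 Pearson chi-square with Yates' continuity correction,
X² = Σ max(|O − E| − 0.5, 0)² / E with 1 df; deficits against a known
expected rate use the exact binomial lower tail.

## Worked example

The package ships a 72-variant worked example (synthetic contig `chrS`,
six gene models, per-(cell type, mark) peak tracks for a lymphoblastoid
B-cell line, CD14+ monocytes and A549 epithelial cells, and an eQTL
table). `examples/01_variant_location.py` prints:

```
                 count   pct
location
exonic_missense      4   5.6
utr5                 2   2.8
utr3                 1   1.4
intronic            40  55.6
upstream            12  16.7
downstream           7   9.7
intergenic           6   8.3
```

— 40/72 (55.6%) of the variants are intronic and only 4 (5.6%) are coding
missense changes; "intergenic" means more than 10 kb from any transcript.
`examples/02_regulatory_classification.py` then applies the chromatin
rules in multi-cell scope:

```
           count   pct
flag
promoter      21  29.2
enhancer      41  56.9
insulator      5   6.9
dnase         34  47.2
eqtl          12  16.7
no_flag        5   6.9
coverage      68  94.4
```

94.4% of the panel carries regulatory evidence (the coverage row counts
any flag or a TF-binding hit); only five variants have none of the five
flags, far below the ~56% no-annotation rate expected for random
variants (exact binomial lower tail ≈ 8×10⁻¹⁹, see
`regumap.gof_expected_rate`). The other examples walk through LD
expansion on a simulated panel, recovery of a planted cell-type-specific
enrichment, and a per-locus activity table.

The same operations are available from a thin CLI (`regumap locate`,
`classify`, `ld-expand`, `enrich`, `compare-cells`, `locus`,
`fixture`); run `regumap --help`.

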
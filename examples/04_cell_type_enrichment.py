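"""Recover a planted cell-type-specific enrichment and test its specificity.

Simulates peak tracks for three cell types where 500 target variants are
covered 5-fold above the 2% background — but only in the B-cell line.
Fold enrichment against the background rate recovers the planted factor,
and the Yates-corrected chi-square comparison against the epithelial
reference singles out the planted cell type.
"""

from regumap import SimulationConfig, Variant, cross_cell_comparison, fold_enrichment, gen_peak_tracks

cfg = SimulationConfig(
    seed=4, background_peak_fraction=0.02, planted_fold=5.0,
    cells=("GM12878", "CD14", "A549"), marks=("H3K27Ac", "H3K4me3"),
)
targets = [Variant(f"t{i}", "chrS", 1_000 + 2_000 * i, "A", "G") for i in range(500)]
tracks = gen_peak_tracks(cfg, targets)

b_track = next(t for t in tracks if t.cell == "GM12878" and t.mark == "H3K27Ac")
res = fold_enrichment(targets, b_track, cfg.background_peak_fraction)
print(
    f"H3K27Ac in GM12878: {res.k_query}/{res.n_query} targets covered, "
    f"fold = {res.fold:.1f} [{res.fold_ci_low:.1f}, {res.fold_ci_high:.1f}], "
    f"p = {res.p_value:.2g}"
)

df = cross_cell_comparison(
    targets, ["H3K27Ac", "H3K4me3"], ["GM12878", "CD14", "A549"], "A549", tracks
)
print("\nper-mark chi-square vs the A549 reference (a = overlaps in that cell):")
print(df[["mark", "cell", "a", "c", "chi2", "p"]].to_string(index=False))
print("\nOnly the planted cell (GM12878) departs from the reference.")
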
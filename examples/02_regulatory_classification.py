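"""Flag promoter/enhancer/insulator/DNase/eQTL status for each variant.

Applies the chromatin rules to the worked example in multi-cell scope
(the union of all cell types' tracks per mark): PolII occupancy makes a
promoter, activating/repressive histone marks without PolII make an
enhancer, CTCF makes an insulator.  The final "coverage" row is the
fraction of variants with any regulatory evidence at all, including
TF-binding-only hits.
"""

from regumap import classify_all, coverage_summary, load_ss72

fx = load_ss72()
calls = classify_all(fx.variants, fx.tracks, eqtl=fx.eqtl)
summary = coverage_summary(calls)
print(summary)
n_unflagged = summary.loc["no_flag", "count"]
print(
    f"\n{summary.loc['coverage', 'pct']}% of variants carry regulatory evidence; "
    f"only {n_unflagged} of {len(calls)} have none of the five flags."
)
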
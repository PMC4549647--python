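"""Enrichment and contingency statistics against independent oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from regumap import (
    ContingencyTable2x2,
    PeakTrack,
    Variant,
    cross_cell_comparison,
    fold_enrichment,
    gof_expected_rate,
    yates_chi2,
)
from regumap.stats import fisher_exact, pearson_chi2

from conftest import variant_at

cell_counts = st.integers(min_value=0, max_value=60)


def binom_tail_brute(k, n, p, lower=True):
    """Direct pmf summation, the exact-oracle for binomial tails."""
    total = 0.0
    rng = range(0, k + 1) if lower else range(k, n + 1)
    for i in rng:
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


class TestYatesChi2:
    def test_diagonal_table_statistic_by_direct_formula(self):
        # E = 5 in every cell, |O-E| = 5, corrected 4.5: 4 * 4.5^2 / 5 = 16.2
        res = yates_chi2(ContingencyTable2x2(10, 0, 0, 10))
        assert res.statistic == pytest.approx(16.2, abs=1e-12)
        assert res.dof == 1

    def test_identical_rows_give_zero(self):
        with pytest.warns(UserWarning, match="below 5"):
            res = yates_chi2(ContingencyTable2x2(7, 3, 7, 3))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_correction_clamps_at_zero(self):
        # |ad - bc| / N = 1/5 < 0.5 in every cell: statistic clamps to 0
        with pytest.warns(UserWarning, match="below 5"):
            res = yates_chi2(ContingencyTable2x2(2, 1, 1, 1))
        assert res.statistic == 0.0

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chi2(ContingencyTable2x2(0, 5, 0, 7))

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="below 5"):
            yates_chi2(ContingencyTable2x2(1, 2, 3, 1))

    @given(a=cell_counts, b=cell_counts, c=cell_counts, d=cell_counts)
    def test_yates_never_exceeds_pearson(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        table = ContingencyTable2x2(a, b, c, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert yates_chi2(table).statistic <= pearson_chi2(table).statistic + 1e-12

    @given(a=cell_counts, b=cell_counts, c=cell_counts, d=cell_counts)
    def test_agrees_with_scipy_when_correction_does_not_overshoot(self, a, b, c, d):
        # scipy shifts O by 0.5 toward E without clamping, so compare only
        # where |O - E| >= 0.5 and both definitions coincide
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        if (np.abs(obs - exp) < 0.5).any():
            return
        table = ContingencyTable2x2(a, b, c, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mine = yates_chi2(table)
        ref_stat, ref_p, _, _ = sps.chi2_contingency(obs, correction=True)
        assert mine.statistic == pytest.approx(ref_stat, rel=1e-10)
        assert mine.p_value == pytest.approx(ref_p, rel=1e-8)

    def test_fisher_fallback_matches_scipy(self):
        assert fisher_exact(ContingencyTable2x2(1, 9, 11, 3)) == pytest.approx(
            sps.fisher_exact([[1, 9], [11, 3]])[1]
        )


class TestGoodnessOfFit:
    @pytest.mark.parametrize("k,n,p", [(5, 72, 0.562), (0, 10, 0.3), (40, 72, 0.562), (120, 200, 0.5)])
    def test_lower_tail_matches_brute_force_summation(self, k, n, p):
        res = gof_expected_rate(k, n, p)
        assert res.p_lower == pytest.approx(binom_tail_brute(k, n, p), abs=1e-12)

    def test_count_at_expectation_sits_mid_tail(self):
        n, p = 72, 0.5
        res = gof_expected_rate(round(n * p), n, p)
        assert 0.3 < res.p_lower < 0.7

    def test_full_count_with_rate_near_one_tends_to_one(self):
        res = gof_expected_rate(72, 72, 0.999)
        assert res.p_lower == 1.0

    def test_chi2_alternative_tracks_the_exact_test(self):
        res = gof_expected_rate(5, 72, 0.562)
        assert res.p_chi2 < 1e-6 and res.p_lower < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gof_expected_rate(80, 72, 0.5)
        with pytest.raises(ValueError):
            gof_expected_rate(5, 72, 1.0)


def grid_variants(n, spacing=1000, start=10_000, chrom="chrT"):
    return [variant_at(start + i * spacing, vid=f"q{i}", chrom=chrom) for i in range(n)]


def track_over(variants, subset_idx, cell="B", mark="DNase"):
    ivals = [
        (v.chrom, v.pos - 1, v.pos) for i, v in enumerate(variants) if i in subset_idx
    ]
    return PeakTrack(cell, mark, ivals)


class TestFoldEnrichment:
    def test_query_equal_to_background_set_gives_fold_one(self):
        variants = grid_variants(50)
        track = track_over(variants, set(range(0, 50, 5)))
        res = fold_enrichment(variants, track, variants)
        assert res.fold == pytest.approx(1.0)

    def test_zero_overlap_gives_zero_fold_and_p_one(self):
        variants = grid_variants(20)
        track = track_over(variants, set())
        res = fold_enrichment(variants, track, 0.1)
        assert res.fold == 0.0 and res.p_value == 1.0

    def test_binomial_p_is_upper_tail(self):
        variants = grid_variants(30)
        track = track_over(variants, set(range(12)))  # k=12 of 30, rate 0.1
        res = fold_enrichment(variants, track, 0.1)
        assert res.p_value == pytest.approx(binom_tail_brute(12, 30, 0.1, lower=False), abs=1e-12)

    def test_permutation_agrees_with_binomial_for_rate_background(self):
        variants = grid_variants(60)
        track = track_over(variants, set(range(20)))
        b = fold_enrichment(variants, track, 0.15, method="binomial")
        p = fold_enrichment(variants, track, 0.15, method="permutation", n_perm=20_000, seed=5)
        assert abs(b.p_value - p.p_value) < 0.02

    def test_zero_background_with_overlap_is_error(self):
        variants = grid_variants(10)
        track = track_over(variants, {0})
        with pytest.raises(ValueError, match="infinite fold"):
            fold_enrichment(variants, track, 0.0)

    def test_empty_query_is_error(self):
        track = PeakTrack("B", "DNase", [])
        with pytest.raises(ValueError, match="empty query"):
            fold_enrichment([], track, 0.1)

    def test_confidence_interval_brackets_the_estimate(self):
        variants = grid_variants(100)
        track = track_over(variants, set(range(30)))
        res = fold_enrichment(variants, track, 0.1)
        assert res.fold_ci_low <= res.fold <= res.fold_ci_high


class TestCrossCellComparison:
    def test_identical_tracks_give_null_everywhere(self):
        variants = grid_variants(40)
        hit = set(range(10))
        tracks = [
            track_over(variants, hit, cell=c, mark="H3K4me3") for c in ("A", "B", "C")
        ]
        df = cross_cell_comparison(variants, ["H3K4me3"], ["A", "B", "C"], "A", tracks)
        assert (df["chi2"] == 0.0).all() and (df["p"] == 1.0).all()

    def test_swapping_cells_leaves_statistic_unchanged(self):
        variants = grid_variants(40)
        t1 = track_over(variants, set(range(25)), cell="A", mark="H3K9Ac")
        t2 = track_over(variants, set(range(8)), cell="B", mark="H3K9Ac")
        d_ab = cross_cell_comparison(variants, ["H3K9Ac"], ["A", "B"], "B", [t1, t2])
        d_ba = cross_cell_comparison(variants, ["H3K9Ac"], ["A", "B"], "A", [t1, t2])
        assert d_ab.loc[0, "chi2"] == pytest.approx(d_ba.loc[0, "chi2"])
        assert d_ab.loc[0, "p"] == pytest.approx(d_ba.loc[0, "p"])

    def test_missing_track_is_error(self):
        variants = grid_variants(10)
        t1 = track_over(variants, set(), cell="A")
        with pytest.raises(ValueError, match="no track"):
            cross_cell_comparison(variants, ["DNase"], ["A", "B"], "A", [t1])

    def test_bh_adjustment_adds_monotone_q_column(self):
        variants = grid_variants(40)
        tracks = [
            track_over(variants, set(range(k)), cell=c, mark=m)
            for (c, m, k) in [
                ("A", "H3K4me3", 30), ("B", "H3K4me3", 5),
                ("A", "H3K9Ac", 12), ("B", "H3K9Ac", 10),
            ]
        ]
        df = cross_cell_comparison(
            variants, ["H3K4me3", "H3K9Ac"], ["A", "B"], "B", tracks, adjust=True
        )
        assert "q" in df.columns and (df["q"] >= df["p"] - 1e-12).all()
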
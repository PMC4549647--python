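"""Genic-location classification, checked against a brute-force oracle."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from regumap import GeneModel, Variant, call_missense, classify_location, summarize_locations
from regumap.locate import LOCATION_CLASSES, classify_locations

from conftest import variant_at


def brute_force_class(pos, genes, flank_bp=10_000):
    """Independent per-base labelling straight from the rule statement."""
    candidates = []
    best_far = None
    for g in genes:
        if g.tx_start <= pos <= g.tx_end:
            if any(s <= pos <= e for s, e in g.cds):
                cls = "cds"
            elif any(s <= pos <= e for s, e in g.utr5):
                cls = "utr5"
            elif any(s <= pos <= e for s, e in g.utr3):
                cls = "utr3"
            elif any(s <= pos <= e for s, e in g.exons):
                cls = "exonic_other"
            else:
                donors = set()
                for is_, ie in g.introns:
                    if g.strand == "+":
                        donors |= {is_, min(is_ + 1, ie)}
                    else:
                        donors |= {ie, max(ie - 1, is_)}
                cls = "splice_donor" if pos in donors else "intronic"
            candidates.append((0, g.gene_id, cls))
        else:
            d = g.tx_start - pos if pos < g.tx_start else pos - g.tx_end
            if d <= flank_bp:
                before = pos < g.tx_start
                if g.strand == "+":
                    cls = "upstream" if before else "downstream"
                else:
                    cls = "downstream" if before else "upstream"
                candidates.append((d, g.gene_id, cls))
            if best_far is None or d < best_far[0]:
                best_far = (d, g.gene_id)
    if candidates:
        return min(candidates)[2]
    return "intergenic"


class TestOracleAgreement:
    def test_every_base_of_a_toy_contig(self, toy_gene, toy_gene_minus):
        toy_gene_minus.gene_id = "zz_minus"
        toy_gene_minus.tx_start += 12_000
        toy_gene_minus.tx_end += 12_000
        toy_gene_minus.exons = [(s + 12_000, e + 12_000) for s, e in toy_gene_minus.exons]
        toy_gene_minus.cds = [(s + 12_000, e + 12_000) for s, e in toy_gene_minus.cds]
        genes = [toy_gene, toy_gene_minus]
        for pos in range(1, 30_000, 7):  # dense scan incl. all boundaries +-
            expected = brute_force_class(pos, genes)
            got = classify_location(variant_at(pos, ref="C", alt="T"), genes).primary_class
            if expected == "cds":
                assert got in ("exonic_missense", "exonic_other"), pos
            else:
                assert got == expected, pos

    def test_exact_boundary_positions(self, toy_gene):
        genes = [toy_gene]
        for pos in [999, 1000, 1299, 1300, 1301, 1302, 1303, 1699, 1700, 1999, 2000, 11_999, 12_000, 12_001]:
            expected = brute_force_class(pos, genes)
            got = classify_location(variant_at(pos, ref="C", alt="T"), genes).primary_class
            if expected == "cds":
                expected_set = {"exonic_missense", "exonic_other"}
            else:
                expected_set = {expected}
            assert got in expected_set, pos


class TestSpliceDonor:
    def test_plus_strand_first_two_intron_bases(self, toy_gene):
        # intron is [1300, 1699]; donor side is 5' (left) on + strand
        for pos, cls in [(1300, "splice_donor"), (1301, "splice_donor"), (1302, "intronic"),
                         (1698, "intronic"), (1699, "intronic")]:
            got = classify_location(variant_at(pos), [toy_gene]).primary_class
            assert got == cls, pos

    def test_minus_strand_donor_is_genomically_right(self, toy_gene_minus):
        for pos, cls in [(1699, "splice_donor"), (1698, "splice_donor"), (1697, "intronic"),
                         (1300, "intronic"), (1301, "intronic")]:
            got = classify_location(variant_at(pos), [toy_gene_minus]).primary_class
            assert got == cls, pos


class TestMissense:
    def test_third_position_wobble_is_synonymous(self, toy_gene):
        # GGA -> GGG, both glycine
        v = variant_at(1002, ref="A", alt="G")
        assert call_missense(v, toy_gene) is False

    def test_first_position_change_is_missense(self, toy_gene):
        # GGA -> AGA, Gly -> Arg
        v = variant_at(1000, ref="G", alt="A")
        assert call_missense(v, toy_gene) is True

    def test_stop_gain_is_not_missense(self):
        g = GeneModel(
            "gstop", "chrT", "+", 100, 105, exons=[(100, 105)], cds=[(100, 105)],
            cds_seq="TACGGA",
        )
        v = variant_at(102, ref="C", alt="A")  # TAC (Tyr) -> TAA (stop)
        assert call_missense(v, g) is False

    def test_minus_strand_uses_reverse_complement(self):
        # coding GGA GGA; genomic plus strand is revcomp(cds) = TCCTCC
        g = GeneModel(
            "gm", "chrT", "-", 100, 105, exons=[(100, 105)], cds=[(100, 105)],
            cds_seq="GGAGGA",
        )
        # genomic pos 105 is coding offset 0; plus-strand C -> T means
        # coding G -> A: GGA -> AGA, missense
        assert call_missense(variant_at(105, ref="C", alt="T"), g) is True
        # genomic pos 103 is coding offset 2 (wobble): GGA -> GGT, silent
        assert call_missense(variant_at(103, ref="T", alt="A"), g) is False

    def test_ref_mismatch_and_ambiguous_base_error(self, toy_gene):
        with pytest.raises(ValueError, match="does not match"):
            call_missense(variant_at(1000, ref="T", alt="C"), toy_gene)
        with pytest.raises(ValueError, match="ambiguous"):
            call_missense(variant_at(1000, ref="G", alt="N"), toy_gene)

    def test_variant_outside_cds_is_error(self, toy_gene):
        with pytest.raises(ValueError, match="not in the CDS"):
            call_missense(variant_at(1500, ref="A", alt="G"), toy_gene)


class TestFlanksAndPrecedence:
    def test_ten_kb_flank_defines_intergenic(self, toy_gene):
        call = classify_location(variant_at(17_000), [toy_gene])
        assert call.primary_class == "intergenic"
        assert call.distance_to_gene == 17_000 - toy_gene.tx_end

    def test_three_kb_upstream_plus_strand(self):
        g = GeneModel("gup", "chrT", "+", 20_000, 21_000, exons=[(20_000, 21_000)])
        call = classify_location(variant_at(17_000), [g])
        assert call.primary_class == "upstream" and call.gene_id == "gup"
        assert call.distance_to_gene == 3_000

    def test_strand_mirror_swaps_upstream_downstream(self, toy_gene, toy_gene_minus):
        v_before = variant_at(toy_gene.tx_start - 500)
        v_after = variant_at(toy_gene.tx_end + 500)
        assert classify_location(v_before, [toy_gene]).primary_class == "upstream"
        assert classify_location(v_after, [toy_gene]).primary_class == "downstream"
        assert classify_location(v_before, [toy_gene_minus]).primary_class == "downstream"
        assert classify_location(v_after, [toy_gene_minus]).primary_class == "upstream"

    def test_nearest_gene_wins_then_lexicographic(self):
        ga = GeneModel("ga", "chrT", "+", 1000, 2000, exons=[(1000, 2000)])
        gb = GeneModel("gb", "chrT", "+", 10_000, 11_000, exons=[(10_000, 11_000)])
        # 2500 is 500 from ga, 7500 from gb -> ga downstream
        assert classify_location(variant_at(2500), [ga, gb]).gene_id == "ga"
        # equidistant: 6000 is 4000 from both -> lexicographic ga
        assert classify_location(variant_at(6000), [ga, gb]).gene_id == "ga"

    def test_unknown_contig_is_error(self, toy_gene):
        with pytest.raises(ValueError, match="contig"):
            classify_location(Variant("x", "chrZ", 5, "A", "G"), [toy_gene])


class TestSummaries:
    @given(st.lists(st.integers(min_value=1, max_value=30_000), min_size=1, max_size=60))
    def test_class_counts_always_partition(self, toy_gene, positions):
        variants = [variant_at(p, vid=f"v{i}") for i, p in enumerate(positions)]
        calls = classify_locations(variants, [toy_gene])
        summary = summarize_locations(calls)
        assert summary["count"].sum() == len(variants)
        assert set(summary.index) == set(LOCATION_CLASSES)

    def test_single_variant_is_its_class_at_100_pct(self, toy_gene):
        calls = classify_locations([variant_at(1500)], [toy_gene])
        summary = summarize_locations(calls)
        assert summary.loc["intronic", "count"] == 1
        assert summary.loc["intronic", "pct"] == 100.0
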
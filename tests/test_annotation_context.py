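"""Fisher tests, regulatory enrichment, orientation and context labels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tevkit.annotation_context import (
    CONTEXT_LABELS, ContextIndex, class_contribution_test, classify_context,
    classify_contexts, context_comparison, fisher_two_sided,
    orientation_concordance, regulatory_enrichment,
)
from tevkit.io_catalog import GeneModel, TevVariant


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric summation."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, n - (N - K)), min(K, n)
    pmf = {k: stats.hypergeom.pmf(k, N, K, n) for k in range(lo, hi + 1)}
    observed = pmf[a]
    return sum(p for p in pmf.values() if p <= observed * (1 + 1e-7))


def _v(vid, pos, te_class="Alu", strand="+", chrom="chr1", length=300,
       deletion=False):
    return TevVariant(vid, chrom, pos, te_class, strand, deletion, length,
                      np.zeros(4))


class TestFisher:
    def test_disjoint_table_matches_hand_enumeration(self):
        # (5,0) vs (0,5): 2 * C(5,5)C(5,0)/C(10,5) = 2/252
        assert fisher_two_sided([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_identical_proportions_give_p_one(self):
        assert fisher_two_sided([[10, 10], [10, 10]]) == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_equals_hypergeometric_summation(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            assert fisher_two_sided([[0, 0], [0, 0]]) == 1.0
            return
        assert fisher_two_sided([[a, b], [c, d]]) == \
            pytest.approx(min(fisher_oracle(a, b, c, d), 1.0), abs=1e-10)

    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_symmetric_under_row_and_column_swap(self, cells):
        a, b, c, d = cells
        p = fisher_two_sided([[a, b], [c, d]])
        assert fisher_two_sided([[c, d], [a, b]]) == pytest.approx(p, abs=1e-12)
        assert fisher_two_sided([[b, a], [d, c]]) == pytest.approx(p, abs=1e-12)


class TestClassContribution:
    def test_extreme_class_skew_significant(self):
        p = class_contribution_test({"SVA": 406, "Alu": 7208},
                                    {"SVA": 35, "Alu": 267})
        assert p[("Alu", "SVA")] < 1e-4

    def test_balanced_tables_near_one(self):
        p = class_contribution_test({"A": 100, "B": 100}, {"A": 10, "B": 10})
        assert p[("A", "B")] >= 0.99

    def test_significant_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            class_contribution_test({"A": 5}, {"A": 6})


class TestOrientation:
    GENES = [GeneModel("g+", "chr1", 1_000, 2_000, "+"),
             GeneModel("g-", "chr1", 5_000, 6_000, "-")]

    def test_same_strand_is_concordant(self):
        table = orientation_concordance([_v("v1", 1_500, strand="+")], self.GENES)
        assert table.concordant == {"Alu": 1} and table.discordant == {}

    def test_opposite_strand_is_discordant(self):
        table = orientation_concordance([_v("v1", 5_500, strand="+")], self.GENES)
        assert table.discordant == {"Alu": 1}

    def test_unknown_strand_bucketed_separately(self):
        table = orientation_concordance([_v("v1", 1_500, strand=None)], self.GENES)
        assert table.unoriented == {"Alu": 1}
        assert table.concordant == {} and table.discordant == {}

    def test_intergenic_variant_ignored(self):
        table = orientation_concordance([_v("v1", 3_000)], self.GENES)
        assert table.to_frame().empty

    def test_identical_proportions_fisher_one(self):
        variants = ([_v(f"a{i}", 1_500, "Alu", "+") for i in range(10)]
                    + [_v(f"b{i}", 5_500, "Alu", "+") for i in range(10)]
                    + [_v(f"c{i}", 1_500, "SVA", "+") for i in range(10)]
                    + [_v(f"d{i}", 5_500, "SVA", "+") for i in range(10)])
        table = orientation_concordance(variants, self.GENES)
        assert table.pairwise_p[("Alu", "SVA")] == pytest.approx(1.0)
        assert table.percent_concordant("Alu") == pytest.approx(50.0)

    def test_disjoint_orientations_hand_computed_p(self):
        variants = ([_v(f"a{i}", 1_500, "Alu", "+") for i in range(5)]
                    + [_v(f"d{i}", 5_500, "SVA", "+") for i in range(5)])
        table = orientation_concordance(variants, self.GENES)
        assert table.pairwise_p[("Alu", "SVA")] == pytest.approx(2 / 252)


class TestRegulatoryEnrichment:
    SIZES = {"chr1": 10_000_000}

    def test_variants_inside_sparse_regulatory_set_enriched(self):
        # regulatory covers 10% of the genome; all variants placed inside it
        reg = [("chr1", i * 1_000_000, i * 1_000_000 + 100_000) for i in range(10)]
        variants = [_v(f"v{i}", i * 1_000_000 + 50_000) for i in range(10)] * 3
        out = regulatory_enrichment({"Alu": variants}, reg, self.SIZES,
                                    R=60, seed=4)
        cell = next(s for s in out if s.unit == "Alu:regulatory")
        assert cell.z > 3 and cell.direction == "enriched"
        anti = next(s for s in out if s.unit == "Alu:non_regulatory")
        assert anti.z < -3 and anti.direction == "depleted"

    def test_genome_wide_regulatory_degenerate_sd_flagged(self):
        reg = [("chr1", 0, 10_000_000)]
        out = regulatory_enrichment({"Alu": [_v("v1", 5_000)]}, reg,
                                    self.SIZES, R=10, seed=1)
        cell = next(s for s in out if s.unit == "Alu:regulatory")
        assert cell.observed == 100.0 and cell.degenerate_sd

    def test_empty_class_reported_not_applicable(self):
        out = regulatory_enrichment({"SVA": []}, [("chr1", 0, 10)],
                                    self.SIZES, R=5, seed=0)
        assert all(s.direction == "not_applicable" for s in out)

    def test_uniform_variants_usually_neutral(self):
        rng = np.random.default_rng(6)
        reg = [("chr1", int(p), int(p) + 5_000)
               for p in rng.integers(0, 9_900_000, 100)]
        flags = []
        for seed in range(12):
            variants = [_v(f"v{i}", int(p)) for i, p in
                        enumerate(rng.integers(1, 10_000_000, 120))]
            out = regulatory_enrichment({"Alu": variants}, reg, self.SIZES,
                                        R=40, seed=seed)
            cell = next(s for s in out if s.unit == "Alu:regulatory")
            flags.append(abs(cell.z) <= 3)
        assert np.mean(flags) >= 0.9


class TestContext:
    GENE = GeneModel(
        "g1", "chr1", 1_000, 10_000, "+", "protein_coding",
        substructure=[("five_prime_utr", 1_000, 1_200),
                      ("exon", 1_200, 2_000),
                      ("intron", 2_000, 8_000),
                      ("exon", 8_000, 9_000),
                      ("three_prime_utr", 9_000, 10_000)])

    def test_precedence_utr3_over_exon(self):
        # deletion-coded span covering both the last exon and the 3'UTR
        v = _v("v1", 8_500, length=1_000, deletion=True)
        assert classify_context(v, [self.GENE]) == "three_prime_utr"

    def test_each_feature_labelled(self):
        expected = {1_100: "five_prime_utr", 1_500: "exon", 5_000: "intron",
                    9_500: "three_prime_utr", 20_000: "intergenic"}
        for pos, label in expected.items():
            assert classify_context(_v("v", pos), [self.GENE]) == label

    def test_labels_partition_variant_set(self):
        rng = np.random.default_rng(2)
        variants = [_v(f"v{i}", int(p))
                    for i, p in enumerate(rng.integers(1, 30_000, 200))]
        labels = classify_contexts(variants, ContextIndex([self.GENE]))
        assert len(labels) == 200
        assert all(lab in CONTEXT_LABELS for lab in labels)

    def test_planted_utr3_skew_detected(self):
        rng = np.random.default_rng(13)
        # background: 5% in 3'UTR; subset: 30%
        def draws(n, frac_utr):
            out = []
            for i in range(n):
                if rng.random() < frac_utr:
                    pos = int(rng.integers(9_000, 10_000))
                else:
                    pos = int(rng.integers(20_000, 50_000))
                out.append(_v(f"x{i}", pos))
            return out
        index = ContextIndex([self.GENE])
        sub = classify_contexts(draws(1_000, 0.30), index)
        background = classify_contexts(draws(10_000, 0.05), index)
        df = context_comparison(sub, background).set_index("context")
        row = df.loc["three_prime_utr"]
        assert row.log2_ratio > 0
        assert row.fisher_p < 1e-3
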
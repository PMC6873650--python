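"""Additive-model fits, BH adjustment, cis pairing and scan invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tevkit.eqtl_engine import (
    bh_adjust, build_cis_pairs, build_covariate_design, fit_additive_model,
    permutation_validation, run_scan,
)
from tevkit.io_catalog import ExpressionMatrix, GeneModel, SampleInfo, TevVariant
from tevkit.synthetic_data import make_scan_dataset


def ols_oracle(y, X):
    """Textbook normal-equations OLS: beta, se, t, p for each coefficient."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


def _random_instance(rng, n):
    g = rng.integers(0, 3, size=n).astype(float)
    while len(np.unique(g)) < 2:
        g = rng.integers(0, 3, size=n).astype(float)
    cohort = [SampleInfo(f"s{i}", rng.choice(["male", "female"]),
                         rng.choice(["P1", "P2", "P3"])) for i in range(n)]
    cov = build_covariate_design(cohort)
    y = rng.normal(size=n) + 0.3 * g
    return y, g, cov


class TestFitAdditiveModel:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(15, 51))
            y, g, cov = _random_instance(rng, n)
            fit = fit_additive_model(y, g, cov)
            if fit.status != "ok":
                continue
            X = np.column_stack([np.ones(n), g, cov.to_numpy()])
            beta, se, t, p = ols_oracle(y, X)
            assert fit.beta == pytest.approx(beta[1], rel=1e-8)
            assert fit.se == pytest.approx(se[1], rel=1e-8)
            assert fit.t == pytest.approx(t[1], rel=1e-8)
            assert fit.p == pytest.approx(p[1], rel=1e-8, abs=1e-300)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 40
        y, g, cov = _random_instance(rng, n)
        X = np.column_stack([np.ones(n), g, cov.to_numpy()])
        res = sm.OLS(y, X).fit()
        fit = fit_additive_model(y, g, cov)
        assert fit.beta == pytest.approx(res.params[1], rel=1e-10)
        assert fit.se == pytest.approx(res.bse[1], rel=1e-10)
        assert fit.p == pytest.approx(res.pvalues[1], rel=1e-8)

    def test_noiseless_line_is_perfect_fit(self):
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=float)
        y = 3.0 + 2.0 * g
        fit = fit_additive_model(y, g, None)
        assert fit.perfect_fit and fit.p == 0.0
        assert fit.beta == pytest.approx(2.0, abs=1e-12)

    def test_monomorphic_dosage_skipped(self):
        fit = fit_additive_model(np.arange(8.0), np.ones(8), None)
        assert fit.status == "monomorphic"

    def test_missing_dosages_dropped_not_imputed(self):
        g = np.array([0, 1, 2, np.nan, 1, 0, 2, 1], dtype=float)
        y = np.arange(8.0)
        fit = fit_additive_model(y, g, None)
        assert fit.n_used == 7
        keep = ~np.isnan(g)
        X = np.column_stack([np.ones(keep.sum()), g[keep]])
        beta, se, t, p = ols_oracle(y[keep], X)
        assert fit.beta == pytest.approx(beta[1], rel=1e-10)

    def test_collinear_design_skipped(self):
        cohort = [SampleInfo(f"s{i}", "male" if i < 4 else "female", "P1")
                  for i in range(8)]
        cov = build_covariate_design(cohort)
        g = cov["male"].to_numpy().copy()   # dosage identical to covariate
        fit = fit_additive_model(np.arange(8.0), g, cov)
        assert fit.status == "collinear"


class TestBhAdjust:
    def test_all_ones(self):
        assert bh_adjust(np.ones(3)).tolist() == [1.0, 1.0, 1.0]

    def test_hand_applied_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_equals_direct_definition(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        direct = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            direct[i] = running
        np.testing.assert_allclose(q, direct, rtol=1e-12, atol=1e-12)
        assert (q >= p - 1e-12).all()


class TestCisPairs:
    GENES = [GeneModel("g1", "chr1", 500_000, 600_000, "+")]

    def _variant(self, pos, length=300, deletion=False):
        return TevVariant("v1", "chr1", pos, "Alu", "+", deletion, length,
                          np.zeros(4))

    def test_distance_to_gene_interval(self):
        (pair,) = build_cis_pairs([self._variant(100_000)], self.GENES)
        assert pair.distance == 400_000

    def test_exactly_one_megabase_excluded(self):
        genes = [GeneModel("g1", "chr1", 1_100_000, 1_200_000, "+")]
        assert build_cis_pairs([self._variant(100_000)], genes) == []
        genes_in = [GeneModel("g1", "chr1", 1_099_999, 1_200_000, "+")]
        assert len(build_cis_pairs([self._variant(100_000)], genes_in)) == 1

    def test_variant_inside_gene_distance_zero(self):
        (pair,) = build_cis_pairs([self._variant(550_000)], self.GENES)
        assert pair.distance == 0

    def test_deletion_coded_uses_full_interval(self):
        v = self._variant(499_000, length=2_000, deletion=True)
        (pair,) = build_cis_pairs([v], self.GENES)
        assert pair.distance == 0        # span (498999, 500999) reaches the gene

    def test_different_chromosome_never_paired(self):
        v = TevVariant("v1", "chr2", 550_000, "Alu", "+", False, 300, np.zeros(4))
        assert build_cis_pairs([v], self.GENES) == []


def _scan_inputs(n_planted, seed, n_samples=120, n_genes=10, vpg=20):
    cfg, cohort, variants, genes, expr, planted = make_scan_dataset(
        n_samples, n_genes, vpg, n_planted=n_planted, seed=seed)
    pairs = build_cis_pairs(variants, genes)
    return cohort, variants, genes, expr, planted, pairs


class TestRunScan:
    def test_vectorized_scan_equals_per_pair_fit(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(2, seed=9)
        scan = run_scan(pairs, expr, variants, cohort)
        cov = build_covariate_design(cohort)
        gmap = {g: i for i, g in enumerate(expr.gene_ids)}
        vmap = {v.variant_id: v for v in variants}
        for r in scan.results[::37]:
            fit = fit_additive_model(expr.values[gmap[r.gene_id]],
                                     vmap[r.variant_id].dosages, cov)
            assert r.beta == pytest.approx(fit.beta, rel=1e-9)
            assert r.p == pytest.approx(fit.p, rel=1e-8, abs=1e-300)

    def test_bh_family_excludes_skipped_pairs(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(0, seed=10)
        scan = run_scan(pairs, expr, variants, cohort)
        assert len(scan.results) + sum(scan.skipped.values()) == len(pairs)
        assert all(r.q >= r.p - 1e-12 for r in scan.results)

    def test_single_pair_q_equals_p(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(0, seed=11)
        tested = [p for p in pairs
                  if len(np.unique(next(v for v in variants
                                        if v.variant_id == p.variant_id).dosages)) > 1]
        one = run_scan(tested[:1], expr, variants, cohort)
        assert one.results[0].q == pytest.approx(one.results[0].p)

    def test_joint_sample_permutation_leaves_results_unchanged(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(1, seed=12)
        base = run_scan(pairs, expr, variants, cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort))
        cohort2 = [cohort[i] for i in perm]
        variants2 = [TevVariant(v.variant_id, v.chrom, v.pos, v.te_class,
                                v.strand, v.deletion_coded, v.length,
                                v.dosages[perm]) for v in variants]
        expr2 = ExpressionMatrix(expr.gene_ids,
                                 [expr.sample_ids[i] for i in perm],
                                 expr.values[:, perm])
        again = run_scan(pairs, expr2, variants2, cohort2)
        for a, b in zip(base.results, again.results):
            assert a.beta == pytest.approx(b.beta, rel=1e-9, abs=1e-12)
            assert a.p == pytest.approx(b.p, rel=1e-7, abs=1e-300)

    def test_empty_pair_list_yields_empty_result(self):
        cohort, variants, genes, expr, _, _ = _scan_inputs(0, seed=13)
        scan = run_scan([], expr, variants, cohort)
        assert scan.results == [] and scan.skipped == {}


class TestParameterRecovery:
    def test_single_pair_beta_unbiased_over_replicates(self):
        """At n=200, sd 1, beta 1.5, the fitted dosage coefficient is an
        unbiased estimator: its replicate mean stays within 3 MC SE."""
        rng = np.random.default_rng(77)
        betas = []
        for _ in range(200):
            g = rng.binomial(2, 0.3, size=200).astype(float)
            y = 5.0 + 1.5 * g + rng.normal(0, 1.0, 200)
            betas.append(fit_additive_model(y, g, None).beta)
        betas = np.asarray(betas)
        se_mean = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - 1.5) < 3 * se_mean


class TestPermutationValidation:
    def test_planted_bundle_gives_large_z(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(4, seed=14)
        summary = permutation_validation(pairs, expr, variants, cohort,
                                         R=30, seed=1)
        assert summary.z > 3

    def test_replicate_vector_length_and_empirical_p(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(0, seed=15)
        summary = permutation_validation(pairs, expr, variants, cohort,
                                         R=12, seed=2)
        assert len(summary.replicate_counts) == 12
        assert 0 < summary.empirical_p <= 1

    def test_requires_at_least_two_replicates(self):
        cohort, variants, genes, expr, _, pairs = _scan_inputs(0, seed=16)
        with pytest.raises(ValueError):
            permutation_validation(pairs, expr, variants, cohort, R=1, seed=0)
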
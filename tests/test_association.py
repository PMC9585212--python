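"""The per-stratum OLS association engine: closed-form correctness,
invariances, calibration, and equivalence of the batch and per-variant paths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import statsmodels.api as sm

import stratgwas as sg
from oracles import ols_normal_equations
from stratgwas.association import _batch_assoc
from stratgwas.errors import (
    CollinearityError,
    DomainError,
    InsufficientDataError,
)


def _random_design(rng, n=50, p=4):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    return y, X


class TestFitOls:
    def test_perfect_fit_zero_se(self):
        g = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        X = np.column_stack([np.ones(8), g])
        coef, se, df = sg.fit_ols(2.0 * g, X)
        assert coef[1] == pytest.approx(2.0, abs=1e-12)
        assert se[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        y, X = _random_design(rng)
        coef, se, df = sg.fit_ols(y, X)
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(coef, fit.params, rtol=1e-10)
        np.testing.assert_allclose(se, fit.bse, rtol=1e-10)
        assert df == int(fit.df_resid)

    def test_constant_shift_moves_only_intercept(self, rng):
        y, X = _random_design(rng)
        c1, _, _ = sg.fit_ols(y, X)
        c2, _, _ = sg.fit_ols(y + 5.0, X)
        assert c2[0] == pytest.approx(c1[0] + 5.0)
        np.testing.assert_allclose(c2[1:], c1[1:], rtol=1e-10)

    def test_collinearity_names_column(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(CollinearityError, match="dup"):
            sg.fit_ols(rng.normal(size=n), X, ["intercept", "x", "dup"])

    def test_insufficient_data(self, rng):
        with pytest.raises(InsufficientDataError):
            sg.fit_ols(np.ones(3), np.ones((3, 3)))

    @settings(max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=8, max_value=200))
    def test_matches_normal_equations_property(self, seed, n):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, min(6, n - 1)))
        y, X = _random_design(rng, n=n, p=p)
        coef, se, df = sg.fit_ols(y, X)
        b0, s0, df0 = ols_normal_equations(y, X)
        np.testing.assert_allclose(coef, b0, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(se, s0, rtol=1e-8, atol=1e-10)
        assert df == df0


class TestPvalueFromBetaSe:
    def test_zero_beta(self):
        assert sg.pvalue_from_beta_se(0.0, 0.1) == 1.0

    def test_printed_table_value(self):
        # beta 0.539, SE 0.154 at biobank-scale df reproduces the printed
        # 4.64e-4 within the rounding of the 3-decimal inputs
        p = sg.pvalue_from_beta_se(0.539, 0.154, df=np.inf)
        assert p == pytest.approx(4.64e-4, rel=0.015)

    def test_normal_quantile(self):
        assert sg.pvalue_from_beta_se(1.959964, 1.0) == pytest.approx(0.05, rel=1e-5)

    def test_t_reference_at_small_df(self):
        p = sg.pvalue_from_beta_se(2.0, 1.0, df=10)
        assert p == pytest.approx(2 * stats.t.sf(2.0, 10), rel=1e-12)
        assert p > sg.pvalue_from_beta_se(2.0, 1.0, df=np.inf)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            sg.pvalue_from_beta_se(1.0, 0.0)
        with pytest.raises(DomainError):
            sg.pvalue_from_beta_se(1.0, 1.0, df=0)


class TestSnpAssociation:
    def test_monomorphic_flagged_not_raised(self, rng):
        rec = sg.snp_association(
            np.zeros(50, dtype=int), rng.normal(size=50), rng.normal(size=(50, 2)), "v", "Q1"
        )
        assert rec.flagged and np.isnan(rec.beta)
        assert rec.n == 50

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(8)
        n = 5000
        g = rng.binomial(2, 0.3, size=n)
        cov = rng.normal(size=(n, 2))
        y = 0.5 * g + cov @ [0.2, -0.1] + rng.normal(size=n)
        rec = sg.snp_association(g, y, cov, "v", "Q1")
        assert abs(rec.beta - 0.5) < 3 * rec.se

    def test_null_pvalues_uniform(self):
        """p over replicated null fits passes a KS test against U(0,1)."""
        rng = np.random.default_rng(314)
        pvals = []
        for _ in range(400):
            n = 300
            g = rng.binomial(2, 0.3, size=n)
            cov = rng.normal(size=(n, 2))
            y = cov @ [0.2, -0.1] + rng.normal(size=n)
            pvals.append(sg.snp_association(g, y, cov).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_dosages_complete_case(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, size=n)
        g[:20] = -1
        cov = rng.normal(size=(n, 1))
        y = rng.normal(size=n)
        rec = sg.snp_association(g, y, cov)
        assert rec.n == 180
        rec2 = sg.snp_association(g[20:], y[20:], cov[20:])
        assert rec.beta == pytest.approx(rec2.beta, rel=1e-12)

    def test_scale_equivariance(self, rng):
        n = 500
        g = rng.binomial(2, 0.4, size=n)
        cov = rng.normal(size=(n, 2))
        y = 0.3 * g + rng.normal(size=n)
        r1 = sg.snp_association(g, y, cov)
        r2 = sg.snp_association(g, 10.0 * y, cov)
        assert r2.beta == pytest.approx(10 * r1.beta, rel=1e-10)
        assert r2.se == pytest.approx(10 * r1.se, rel=1e-10)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_allele_flip_antisymmetry(self, rng):
        n = 500
        g = rng.binomial(2, 0.4, size=n)
        cov = rng.normal(size=(n, 2))
        y = 0.3 * g + rng.normal(size=n)
        r1 = sg.snp_association(g, y, cov)
        r2 = sg.snp_association(2 - g, y, cov)
        assert r2.beta == pytest.approx(-r1.beta, rel=1e-10)
        assert r2.se == pytest.approx(r1.se, rel=1e-10)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)


class TestStratifiedGwas:
    def test_batch_path_equals_per_variant_path(self):
        """Frisch-Waugh batch results match one-variant-at-a-time OLS."""
        cfg = sg.SimulationConfig(n_individuals=400, n_variants=30, seed=21)
        gm, pheno, _ = sg.simulate_cohort(cfg)
        strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids), k=2)
        res = sg.run_stratified_gwas(gm, pheno, strata)
        label = "Q1"
        in_s = strata.assignments.reindex(pheno.ids).to_numpy() == label
        y = pheno.phenotype()[in_s]
        C = pheno.covariates()[in_s]
        for j, vid in enumerate(gm.variant_ids[:10]):
            rec = sg.snp_association(gm.dosages[in_s, j], y, C, vid, label)
            row = res[label].set_index("SNP").loc[vid]
            assert row["BETA"] == pytest.approx(rec.beta, rel=1e-9)
            assert row["SE"] == pytest.approx(rec.se, rel=1e-9)
            assert row["P"] == pytest.approx(rec.p, rel=1e-6)

    def test_missing_dosage_fallback_matches(self):
        cfg = sg.SimulationConfig(n_individuals=400, n_variants=20, missing_rate=0.05, seed=3)
        gm, pheno, _ = sg.simulate_cohort(cfg)
        strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids), k=2)
        res = sg.run_stratified_gwas(gm, pheno, strata)
        in_s = strata.assignments.reindex(pheno.ids).to_numpy() == "Q2"
        y = pheno.phenotype()[in_s]
        C = pheno.covariates()[in_s]
        frame = res["Q2"].set_index("SNP")
        for j, vid in enumerate(gm.variant_ids):
            rec = sg.snp_association(gm.dosages[in_s, j], y, C, vid, "Q2")
            assert frame.loc[vid, "NMISS"] == rec.n
            if rec.flagged:
                assert np.isnan(frame.loc[vid, "P"])
            else:
                assert frame.loc[vid, "BETA"] == pytest.approx(rec.beta, rel=1e-9)

    def test_null_betas_uncorrelated_between_strata(self):
        cfg = sg.SimulationConfig(n_individuals=2000, n_variants=200, seed=17)
        gm, pheno, _ = sg.simulate_cohort(cfg)
        strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids), k=2)
        res = sg.run_stratified_gwas(gm, pheno, strata)
        r = sg.spearman_correlation(res["Q1"]["BETA"].to_numpy(), res["Q2"]["BETA"].to_numpy())
        assert abs(r) < 0.25  # ~3.5 sd of the null Spearman at m = 200

    def test_age_slope_betas_monotone_across_quartiles(self):
        c = 0.05
        cfg = sg.SimulationConfig(
            n_individuals=8000, n_variants=20, maf_range=(0.3, 0.3), seed=23,
            effects=[sg.EffectSpec("snp00007", age_slope=c)],
        )
        gm, pheno, _ = sg.simulate_cohort(cfg)
        strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids), k=4)
        res = sg.run_stratified_gwas(gm, pheno, strata)
        betas = [res[q].set_index("SNP").loc["snp00007", "BETA"] for q in strata.labels]
        assert betas == sorted(betas)

    def test_deterministic(self):
        cfg = sg.SimulationConfig(n_individuals=300, n_variants=10, seed=5)
        frames = []
        for _ in range(2):
            gm, pheno, _ = sg.simulate_cohort(cfg)
            strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids))
            frames.append(sg.run_stratified_gwas(gm, pheno, strata))
        for q in frames[0]:
            pd.testing.assert_frame_equal(frames[0][q], frames[1][q])

    def test_stratum_too_small(self):
        cfg = sg.SimulationConfig(n_individuals=20, n_variants=5, seed=2)
        gm, pheno, _ = sg.simulate_cohort(cfg)
        strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids), k=4)
        with pytest.raises(InsufficientDataError):
            sg.run_stratified_gwas(gm, pheno, strata)
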
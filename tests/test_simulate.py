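"""The generator must produce the statistical structure the analysis assumes:
HWE genotypes, the configured covariate distributions, and phenotypes whose
per-allele effects vary linearly with age."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stratgwas as sg
from stratgwas.errors import ConfigError, DomainError


def _cfg(**kw):
    return sg.SimulationConfig(**kw)


class TestGenotypes:
    def test_mean_dosage_at_half_maf(self, rng):
        gm = sg.simulate_genotypes(_cfg(n_individuals=10000, n_variants=1, maf_range=(0.5, 0.5)), rng)
        assert abs(gm.dosages.mean() - 1.0) < 0.02

    def test_no_missing_when_rate_zero(self, rng):
        gm = sg.simulate_genotypes(_cfg(n_individuals=500, n_variants=50, missing_rate=0.0), rng)
        assert not (gm.dosages == -1).any()

    def test_missing_rate_honoured(self, rng):
        gm = sg.simulate_genotypes(_cfg(n_individuals=2000, n_variants=50, missing_rate=0.1), rng)
        assert np.mean(gm.dosages == -1) == pytest.approx(0.1, abs=0.01)

    def test_hwe_proportions(self, rng):
        """maf 0.3 genotype counts fit (0.49, 0.42, 0.09) by chi-square GOF."""
        gm = sg.simulate_genotypes(
            _cfg(n_individuals=10000, n_variants=1, maf_range=(0.3, 0.3)), rng
        )
        counts = [int((gm.dosages == d).sum()) for d in (0, 1, 2)]
        expected = np.array([0.49, 0.42, 0.09]) * 10000
        res = stats.chisquare(counts, expected)
        assert res.pvalue > 0.001

    def test_allele_frequency_unbiased(self, rng):
        gm = sg.simulate_genotypes(
            _cfg(n_individuals=20000, n_variants=1, maf_range=(0.2, 0.2)), rng
        )
        assert gm.dosages.mean() / 2 == pytest.approx(0.2, abs=0.01)

    def test_positions_on_configured_map(self, rng):
        gm = sg.simulate_genotypes(_cfg(n_individuals=100, n_variants=10, variant_spacing=5000), rng)
        pos = np.array([v.pos for v in gm.variants])
        assert (np.diff(pos) == 5000).all()

    def test_ld_buddies_have_high_r2(self, rng):
        cfg = _cfg(
            n_individuals=2000,
            n_variants=20,
            maf_range=(0.3, 0.3),
            ld_blocks=[sg.LDBlockSpec("snp00005", n_buddies=2, flip_prob=0.02)],
        )
        gm = sg.simulate_genotypes(cfg, rng)
        assert sg.ld_r2(gm.column("snp00005"), gm.column("snp00006")) > 0.7
        assert sg.ld_r2(gm.column("snp00005"), gm.column("snp00015")) < 0.05


class TestCovariates:
    def test_age_support(self, rng):
        cov = sg.simulate_covariates(_cfg(n_individuals=5000, age_range=(40, 69)), rng)
        assert cov["age"].min() >= 40 and cov["age"].max() <= 69

    def test_all_female_when_fraction_zero(self, rng):
        cov = sg.simulate_covariates(_cfg(n_individuals=200, male_fraction=0.0), rng)
        assert (cov["sex"] == 0).all()

    def test_male_fraction_calibrated(self, rng):
        cov = sg.simulate_covariates(_cfg(n_individuals=50000, male_fraction=0.46), rng)
        assert cov["sex"].mean() == pytest.approx(0.46, abs=0.01)

    def test_age_weights_skew(self, rng):
        w = [1.0] * 15 + [0.0] * 15  # only the younger half of 40-69
        cov = sg.simulate_covariates(_cfg(n_individuals=1000, age_weights=w), rng)
        assert cov["age"].max() <= 54


class TestPhenotype:
    def test_degenerate_noise_recovers_age_line(self, rng):
        cfg = _cfg(
            n_individuals=100, n_variants=5, mu=2.0, age_effect=1.0, sex_effect=0.0,
            pc_effects=0.0, noise_sd=1e-12,
        )
        gm = sg.simulate_genotypes(cfg, rng)
        cov = sg.simulate_covariates(cfg, rng)
        y = sg.simulate_phenotype(gm, cov, cfg, rng)
        np.testing.assert_allclose(y, 2.0 + cov["age"].to_numpy(float), atol=1e-6)

    def test_unknown_effect_variant_rejected(self, rng):
        cfg = _cfg(n_individuals=100, n_variants=5, effects=[sg.EffectSpec("nope", 0.5)])
        gm = sg.simulate_genotypes(cfg, rng)
        cov = sg.simulate_covariates(cfg, rng)
        with pytest.raises(ConfigError, match="nope"):
            sg.simulate_phenotype(gm, cov, cfg, rng)

    def test_constant_effect_recovered_in_every_stratum(self):
        """With no age slope, each stratum's regression estimates a_j."""
        a_j = 0.3
        cfg = _cfg(
            n_individuals=20000, n_variants=10, maf_range=(0.3, 0.3), seed=99,
            effects=[sg.EffectSpec("snp00004", base_effect=a_j, age_slope=0.0)],
        )
        gm, pheno, _ = sg.simulate_cohort(cfg)
        strata = sg.assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids))
        res = sg.run_stratified_gwas(gm, pheno, strata)
        for label, frame in res.items():
            row = frame[frame["SNP"] == "snp00004"].iloc[0]
            assert abs(row["BETA"] - a_j) < 3 * row["SE"], label

    def test_age_slope_gives_monotone_stratum_betas(self):
        """a_j=0, c_j=0.02 -> stratum betas track c_j*(mean age - 55)."""
        cfg = _cfg(
            n_individuals=20000, n_variants=10, maf_range=(0.3, 0.3), seed=42,
            effects=[sg.EffectSpec("snp00004", base_effect=0.0, age_slope=0.02,
                                   reference_age=55.0)],
        )
        gm, pheno, _ = sg.simulate_cohort(cfg)
        ages = pheno.data["age"].to_numpy()
        strata = sg.assign_age_quartiles(ages, list(pheno.ids))
        res = sg.run_stratified_gwas(gm, pheno, strata)
        betas = []
        for label in strata.labels:
            row = res[label][res[label]["SNP"] == "snp00004"].iloc[0]
            mean_age = strata.summary.set_index("stratum").loc[label, "age_mean"]
            assert abs(row["BETA"] - 0.02 * (mean_age - 55.0)) < 3 * row["SE"]
            betas.append(row["BETA"])
        assert betas == sorted(betas)  # monotone with stratum age

    def test_variance_decomposition(self):
        """Var(y) matches genetic + covariate + noise variance within 5%."""
        cfg = _cfg(
            n_individuals=50000, n_variants=5, maf_range=(0.3, 0.3), seed=7,
            effects=[sg.EffectSpec("snp00002", base_effect=0.5)],
        )
        gm, pheno, _ = sg.simulate_cohort(cfg)
        y = pheno.phenotype()
        age_var = (30**2 - 1) / 12.0  # uniform integer on 30 values
        expected = (
            0.5**2 * 2 * 0.3 * 0.7
            + cfg.age_effect**2 * age_var
            + cfg.sex_effect**2 * 0.46 * 0.54
            + cfg.n_pcs * 0.05**2
            + cfg.noise_sd**2
        )
        assert np.var(y) == pytest.approx(expected, rel=0.05)


class TestCompositeTraits:
    def test_bmi_arithmetic(self):
        bmi, _ = sg.derive_composite_traits(81.0, 1.8, 90.0, 100.0)
        assert bmi == pytest.approx(25.0)

    def test_equal_circumferences_give_unit_whr(self):
        _, whr = sg.derive_composite_traits(70.0, 1.7, 95.0, 95.0)
        assert whr == pytest.approx(1.0)

    def test_cohort_scale_whr(self):
        # typical youngest-quartile waist/hip means reproduce WHR ~ 0.85
        _, whr = sg.derive_composite_traits(70.0, 1.7, 88.10, 103.06)
        assert whr == pytest.approx(0.8548, abs=1e-4)
        assert whr == pytest.approx(0.85, abs=0.01)

    def test_nonpositive_denominators_rejected(self):
        with pytest.raises(DomainError):
            sg.derive_composite_traits(81.0, 0.0, 90.0, 100.0)
        with pytest.raises(DomainError):
            sg.derive_composite_traits(81.0, 1.8, 90.0, 0.0)


class TestTruthTable:
    def test_empty(self):
        assert sg.truth_table(_cfg(n_individuals=100, n_variants=5)).empty

    def test_rows_match_inputs(self):
        effects = [
            sg.EffectSpec("snp00001", 0.1, 0.0),
            sg.EffectSpec("snp00002", 0.0, 0.02),
            sg.EffectSpec("snp00003", 0.0, 0.0),
        ]
        tt = sg.truth_table(_cfg(n_individuals=100, n_variants=5, effects=effects))
        assert len(tt) == 3
        assert tt["causal"].tolist() == [True, True, False]

    def test_ids_contained_in_matrix(self, rng):
        cfg = _cfg(n_individuals=100, n_variants=5, effects=[sg.EffectSpec("snp00003", 0.2)])
        gm = sg.simulate_genotypes(cfg, rng)
        assert set(sg.truth_table(cfg)["variant_id"]) <= set(gm.variant_ids)


class TestWriteDataset:
    def test_round_trip(self, small_cohort, tmp_path):
        gm, pheno, truth = small_cohort
        paths = sg.write_dataset(gm, pheno, truth, tmp_path)
        assert sg.read_vcf(paths["vcf"]) == gm
        back = sg.read_pheno_covar(paths["pheno"], pheno.phenotype_name, pheno.covariate_names)
        assert list(back.ids) == list(pheno.ids)
        assert pd.read_csv(paths["truth"], sep="\t").empty == truth.empty

    def test_empty_cohort_writes_valid_files(self, tmp_path):
        gm = sg.GenotypeMatrix([], np.empty((0, 0), dtype=np.int8), [])
        pheno = sg.PhenotypeTable(
            pd.DataFrame({"IID": [], "age": [], "pheno": []}), "pheno", ["age"]
        )
        paths = sg.write_dataset(gm, pheno, sg.truth_table(_cfg(n_individuals=100)), tmp_path)
        assert sg.read_vcf(paths["vcf"]).n_variants == 0
        assert sg.read_pheno_covar(paths["pheno"], "pheno", ["age"]).n == 0

    def test_seed_determinism(self):
        a = sg.simulate_cohort(_cfg(n_individuals=200, n_variants=20, seed=5))
        b = sg.simulate_cohort(_cfg(n_individuals=200, n_variants=20, seed=5))
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1].phenotype(), b[1].phenotype())


class TestPowerDesign:
    def test_noncentrality_for_power_matches_normal_quantiles(self):
        # two-sided alpha=0.05 at 50% power needs exactly z_{0.025}
        assert sg.noncentrality_for_power(0.05, 0.5) == pytest.approx(1.959964, abs=1e-5)

    def test_slope_scales_inversely_with_sample_size(self):
        c1 = sg.age_slope_for_noncentrality(6.0, 4000, 4, 0.3, 1.0)
        c2 = sg.age_slope_for_noncentrality(6.0, 16000, 4, 0.3, 1.0)
        assert c1 == pytest.approx(2 * c2)
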
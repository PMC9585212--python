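"""Synthetic cohort generator with age-dependent per-allele effects.

The generator emulates the statistical structure the stratified analysis
assumes: a biobank-like cohort of middle-aged to older adults (ages 40-69),
Hardy-Weinberg genotypes at configurable minor-allele frequencies on a
synthetic map, standard GWAS covariates (sex, genotyping-array indicator,
10 Gaussian principal components), and a quantitative trait

    y_i = mu + a_age*age_i + a_sex*sex_i + a_arr*array_i + sum_k g_k*PC_ik
          + sum_j g_ij * (a_j + c_j*(age_i - age_ref)) + eps_i,
    eps_i ~ N(0, noise_sd^2)

so a variant's per-allele effect ``a_j + c_j*(age - age_ref)`` varies
linearly with age. A linear gene-age interaction is the minimal model able
to produce the monotone quartile-wise effect trends the differential test
targets. Missing dosages contribute the variant's mean dosage to the
genetic term (a documented choice that keeps the generative model defined
when missingness is switched on).

Optional LD blocks are induced by copying a source variant's two allele
copies into neighbouring variants with a per-allele flip probability,
giving tunable r^2 for clumping tests (not coalescent-realistic LD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PhenotypeTable, VariantInfo
from .errors import ConfigError, DomainError
from .io import write_pheno_covar, write_vcf


@dataclass(frozen=True)
class EffectSpec:
    """Per-allele genetic effect on the trait, linear in age.

    ``base_effect`` is trait units per a1 allele at ``reference_age``;
    ``age_slope`` is trait units per allele per year.
    """

    variant_id: str
    base_effect: float = 0.0
    age_slope: float = 0.0
    reference_age: float = 55.0

    @property
    def causal(self) -> bool:
        return self.base_effect != 0.0 or self.age_slope != 0.0


@dataclass(frozen=True)
class LDBlockSpec:
    """Copy ``source_id``'s alleles into its next ``n_buddies`` variants,
    flipping each allele copy with probability ``flip_prob``."""

    source_id: str
    n_buddies: int
    flip_prob: float = 0.05


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults sketch a biobank-scale design at desk scale: ages uniform on
    40-69 (integer years), 46% male, array split 50/50, 10 standard-normal
    PCs, and a standardized quantitative trait (noise_sd = 1) with modest
    covariate effects.
    """

    n_individuals: int = 2000
    n_variants: int = 500
    maf_range: tuple = (0.01, 0.5)
    missing_rate: float = 0.0
    age_range: tuple = (40, 69)
    male_fraction: float = 0.46
    n_pcs: int = 10
    mu: float = 0.0
    age_effect: float = 0.02
    sex_effect: float = 0.1
    array_effect: float = 0.0
    pc_effects: object = 0.05  # scalar applied to all PCs, or a length-n_pcs sequence
    effects: list = field(default_factory=list)  # list[EffectSpec] (dicts accepted)
    ld_blocks: list = field(default_factory=list)  # list[LDBlockSpec] (dicts accepted)
    noise_sd: float = 1.0
    chrom: str = "1"
    base_position: int = 1_000_000
    variant_spacing: int = 5_000  # bp between consecutive variants
    age_weights: object = None  # optional per-age sampling weights (skewed cohorts)
    seed: int = 2022

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < min <= max <= 0.5, got {self.maf_range}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        a0, a1 = self.age_range
        if a0 > a1:
            raise ConfigError(f"age_range must be well-ordered, got {self.age_range}")
        if not (0 <= self.male_fraction <= 1):
            raise ConfigError(f"male_fraction must be in [0, 1], got {self.male_fraction}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_individuals < 16:
            raise ConfigError("n_individuals must be >= 16 (4 per stratum for k = 4)")
        if self.variant_spacing < 1:
            raise ConfigError(f"variant_spacing must be >= 1, got {self.variant_spacing}")
        self.effects = [e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects]
        self.ld_blocks = [
            b if isinstance(b, LDBlockSpec) else LDBlockSpec(**b) for b in self.ld_blocks
        ]
        for e in self.effects:
            if not (a0 <= e.reference_age <= a1):
                raise ConfigError(
                    f"effect {e.variant_id}: reference_age {e.reference_age} outside "
                    f"cohort age range {self.age_range}"
                )
        if self.age_weights is not None:
            w = np.asarray(self.age_weights, dtype=float)
            if len(w) != a1 - a0 + 1 or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("age_weights must be non-negative, one per age in age_range")

    def pc_effect_vector(self) -> np.ndarray:
        if np.isscalar(self.pc_effects):
            return np.full(self.n_pcs, float(self.pc_effects))
        v = np.asarray(self.pc_effects, dtype=float)
        if len(v) != self.n_pcs:
            raise ConfigError(f"pc_effects has {len(v)} entries for {self.n_pcs} PCs")
        return v


def _variant_id(j: int) -> str:
    return f"snp{j + 1:05d}"


# ----------------------------------------------------------------------
def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Draw HWE hard-call genotypes on a single synthetic chromosome.

    Each variant's allele frequency is uniform on ``maf_range`` and its
    dosage is the sum of two independent allele draws (binomial(2, maf)).
    LD-block buddies then overwrite their columns by copying the source
    variant's alleles with per-allele flips. Finally entries are masked
    missing with probability ``missing_rate``.
    """
    n, m = config.n_individuals, config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)

    variants = [
        VariantInfo(
            id=_variant_id(j),
            chrom=config.chrom,
            pos=config.base_position + j * config.variant_spacing,
            a1="A",
            a2="G",
        )
        for j in range(m)
    ]
    id_to_col = {v.id: j for j, v in enumerate(variants)}

    for block in config.ld_blocks:
        if block.source_id not in id_to_col:
            raise ConfigError(f"LD block source {block.source_id!r} not among simulated variants")
        src = id_to_col[block.source_id]
        if src + block.n_buddies >= m:
            raise ConfigError(
                f"LD block at {block.source_id} needs {block.n_buddies} following variants"
            )
        g = dosages[:, src].astype(np.int64)
        for b in range(1, block.n_buddies + 1):
            # flip each of the 2 allele copies independently with prob flip_prob
            flipped_alt = rng.binomial(g, block.flip_prob)
            flipped_ref = rng.binomial(2 - g, block.flip_prob)
            dosages[:, src + b] = (g - flipped_alt + flipped_ref).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random(size=dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    return GenotypeMatrix(variants, dosages, [f"ind{i + 1:06d}" for i in range(n)], sort=False)


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ages (uniform or weighted integers), sex, array indicator and Gaussian PCs."""
    n = config.n_individuals
    a0, a1 = config.age_range
    ages_support = np.arange(a0, a1 + 1)
    if config.age_weights is not None:
        w = np.asarray(config.age_weights, dtype=float)
        age = rng.choice(ages_support, size=n, p=w / w.sum())
    else:
        age = rng.integers(a0, a1 + 1, size=n)
    df = pd.DataFrame(
        {
            "IID": [f"ind{i + 1:06d}" for i in range(n)],
            "age": age.astype(int),
            "sex": rng.binomial(1, config.male_fraction, size=n),
            "array": rng.binomial(1, 0.5, size=n),
        }
    )
    pcs = rng.standard_normal(size=(n, config.n_pcs))
    for k in range(config.n_pcs):
        df[f"pc{k + 1}"] = pcs[:, k]
    return df


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quantitative trait with linear covariate effects and age-varying
    per-allele genetic effects (see module docstring for the model)."""
    n = len(covariates)
    if genotypes.n_individuals != n:
        raise ConfigError(
            f"genotypes have {genotypes.n_individuals} individuals, covariates {n}"
        )
    age = covariates["age"].to_numpy(dtype=float)
    y = np.full(n, config.mu, dtype=float)
    y += config.age_effect * age
    y += config.sex_effect * covariates["sex"].to_numpy(dtype=float)
    y += config.array_effect * covariates["array"].to_numpy(dtype=float)
    pc_eff = config.pc_effect_vector()
    for k in range(config.n_pcs):
        y += pc_eff[k] * covariates[f"pc{k + 1}"].to_numpy(dtype=float)

    known = set(genotypes.variant_ids)
    for eff in config.effects:
        if eff.variant_id not in known:
            raise ConfigError(f"EffectSpec references unknown variant {eff.variant_id!r}")
        g = genotypes.column(eff.variant_id).astype(float)
        miss = g == MISSING
        if miss.any():
            g[miss] = g[~miss].mean() if (~miss).any() else 0.0
        y += g * (eff.base_effect + eff.age_slope * (age - eff.reference_age))

    y += rng.normal(0.0, config.noise_sd, size=n)
    return y


def derive_composite_traits(weight, height, wc, hc):
    """BMI = weight/height^2 (kg/m^2) and WHR = waist/hip circumference.

    Accepts scalars or arrays; raises :class:`DomainError` on non-positive
    heights or hip circumferences.
    """
    weight, height = np.asarray(weight, dtype=float), np.asarray(height, dtype=float)
    wc, hc = np.asarray(wc, dtype=float), np.asarray(hc, dtype=float)
    if np.any(height <= 0):
        raise DomainError("height must be > 0 to compute BMI")
    if np.any(hc <= 0):
        raise DomainError("hip circumference must be > 0 to compute WHR")
    bmi = weight / height**2
    whr = wc / hc
    if bmi.ndim == 0:
        return float(bmi), float(whr)
    return bmi, whr


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """The exact effects :func:`simulate_phenotype` applies, with causal flags."""
    rows = [
        {
            "variant_id": e.variant_id,
            "base_effect": e.base_effect,
            "age_slope": e.age_slope,
            "reference_age": e.reference_age,
            "causal": e.causal,
        }
        for e in config.effects
    ]
    return pd.DataFrame(
        rows, columns=["variant_id", "base_effect", "age_slope", "reference_age", "causal"]
    )


def simulate_cohort(
    config: SimulationConfig, phenotype_name: str = "pheno"
) -> tuple[GenotypeMatrix, PhenotypeTable, pd.DataFrame]:
    """Convenience wrapper: genotypes + covariates + phenotype + truth table.

    Uses a single generator seeded from ``config.seed``; for per-stage
    sub-seeding drive the three simulate_* functions directly.
    """
    rng = np.random.default_rng(config.seed)
    gm = simulate_genotypes(config, rng)
    cov = simulate_covariates(config, rng)
    y = simulate_phenotype(gm, cov, config, rng)
    cov = cov.copy()
    cov[phenotype_name] = y
    covariate_names = ["age", "sex", "array"] + [f"pc{k + 1}" for k in range(config.n_pcs)]
    table = PhenotypeTable(cov, phenotype_name, covariate_names)
    return gm, table, truth_table(config)


def noncentrality_for_power(alpha: float = 5e-8, power: float = 0.9) -> float:
    """Noncentrality a two-sided level-``alpha`` normal test needs for ``power``.

    z_{alpha/2} + z_{power}; e.g. 90% power at the genome-wide threshold
    requires a noncentrality of about 6.73.
    """
    from scipy import stats

    if not (0 < alpha < 1) or not (0 < power < 1):
        raise DomainError("alpha and power must be in (0, 1)")
    return float(stats.norm.isf(alpha / 2.0) + stats.norm.ppf(power))


def age_slope_for_noncentrality(
    target: float,
    n_individuals: int,
    k: int,
    maf: float,
    noise_sd: float,
    age_range: tuple = (40, 69),
) -> float:
    """Age slope c giving an expected differential statistic of ``target``
    between the youngest and oldest of ``k`` equal age strata.

    Assumes ages uniform on ``age_range`` (integer years), HWE dosages at
    ``maf``, and residual noise ``noise_sd``. The per-stratum effect is
    approximately c * (stratum mean age - reference age), and each
    stratum's SE is noise_sd / sqrt(n_s * 2 maf (1 - maf)) with
    n_s = n/k, so

        c = target * sqrt(2) * SE / (mean age Qk - mean age Q1).
    """
    a0, a1 = age_range
    width = (a1 - a0 + 1) / k
    delta_age = (a1 - (width - 1) / 2.0) - (a0 + (width - 1) / 2.0)
    n_s = n_individuals / k
    se = noise_sd / np.sqrt(n_s * 2.0 * maf * (1.0 - maf))
    return float(target * np.sqrt(2.0) * se / delta_age)


def write_dataset(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict:
    """Emit genotypes.vcf, pheno.tsv and truth.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "pheno": out / "pheno.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(genotypes, paths["vcf"])
    write_pheno_covar(phenotypes, paths["pheno"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
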
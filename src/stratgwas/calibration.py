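"""Simulation studies of the differential test: type-I error and power.

These drive the same stage functions as the disk-writing pipeline —
simulate, QC, stratify, per-stratum GWAS, beta correlation, differential
test, clumping — but keep everything in memory so genome-sized null
studies stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import CovariateSpec, run_stratified_gwas
from .clump import greedy_clump
from .config import GENOME_WIDE_P, stage_rng
from .datatypes import PhenotypeTable
from .differential import pairwise_beta_correlation, run_differential
from .qc import QCThresholds, filter_snps
from .simulate import (
    EffectSpec,
    LDBlockSpec,
    SimulationConfig,
    age_slope_for_noncentrality,
    noncentrality_for_power,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype,
)
from .strata import assign_age_quartiles


@dataclass
class StudyResult:
    diff_table: pd.DataFrame
    pair: tuple
    r: float
    loci: list
    n_variants_tested: int


def stratified_diff_study(
    sim_cfg: SimulationConfig,
    k: int = 4,
    pair: tuple = ("Q1", "Q4"),
    qc: QCThresholds | None = None,
    clump: bool = False,
) -> StudyResult:
    """One cohort through the whole analysis, returning the diff table.

    ``pair`` fixes the compared strata (the youngest/oldest quartiles by
    default); the inter-stratum Spearman correlation used in the statistic
    is still estimated from the data for that pair.
    """
    gm = simulate_genotypes(sim_cfg, stage_rng(sim_cfg.seed, "simulate_genotypes"))
    cov = simulate_covariates(sim_cfg, stage_rng(sim_cfg.seed, "simulate_covariates"))
    y = simulate_phenotype(gm, cov, sim_cfg, stage_rng(sim_cfg.seed, "simulate_phenotype"))
    cov = cov.copy()
    cov["pheno"] = y
    cov_names = ["age", "sex", "array"] + [f"pc{i + 1}" for i in range(sim_cfg.n_pcs)]
    pheno = PhenotypeTable(cov, "pheno", cov_names)

    gm, _ = filter_snps(gm, qc or QCThresholds())
    strata = assign_age_quartiles(pheno.data["age"].to_numpy(), list(pheno.ids), k=k)
    stats_by = run_stratified_gwas(gm, pheno, strata, CovariateSpec(cov_names))
    corr = pairwise_beta_correlation(stats_by, strata.labels)
    r = corr.r_for(*pair)
    diff = run_differential(stats_by[pair[0]], stats_by[pair[1]], r_override=r)
    loci = greedy_clump(diff, gm) if clump else []
    return StudyResult(diff, pair, r, loci, len(diff))


def null_calibration(
    n_individuals: int,
    n_variants: int,
    seed: int,
    alpha: float = 0.05,
    k: int = 4,
) -> dict:
    """Differential-test calibration under the global null (no genetic effects).

    Covariate effects stay on. Returns the fraction of P_diff below
    ``alpha``, a Kolmogorov-Smirnov p against Uniform(0,1), the genomic
    inflation lambda, and the number of variants tested.
    """
    sim_cfg = SimulationConfig(n_individuals=n_individuals, n_variants=n_variants, seed=seed)
    res = stratified_diff_study(sim_cfg, k=k, pair=("Q1", f"Q{k}"))
    p = res.diff_table["P_DIFF"].to_numpy()
    chisq = stats.chi2.isf(p, df=1)
    return {
        "fraction_below_alpha": float(np.mean(p < alpha)),
        "ks_pvalue": float(stats.kstest(p, "uniform").pvalue),
        "lambda_gc": float(np.median(chisq) / stats.chi2.ppf(0.5, df=1)),
        "n_variants": int(len(p)),
        "r": res.r,
    }


def power_study(
    n_replicates: int,
    n_individuals: int,
    n_variants: int,
    seed: int,
    maf: float = 0.3,
    alpha: float = GENOME_WIDE_P,
    power_target: float = 0.9,
    k: int = 4,
    n_ld_buddies: int = 0,
) -> dict:
    """Recovery of one planted gene-age interaction across seeded replicates.

    The planted variant has no effect at the reference age and an age
    slope sized analytically for ``power_target`` at the two-sided level
    ``alpha`` (noncentrality z_{alpha/2} + z_{power}). By default it is the
    only variant at its locus (set ``n_ld_buddies`` to surround it with an
    LD block). Reports how often it reaches the genome-wide tier and how
    often it is a clump lead when significant.
    """
    target = noncentrality_for_power(alpha, power_target)
    slope = age_slope_for_noncentrality(target, n_individuals, k, maf, 1.0)
    planted = f"snp{n_variants // 2:05d}"
    n_sig = 0
    n_lead_when_sig = 0
    for rep in range(n_replicates):
        ld = (
            [LDBlockSpec(planted, n_buddies=n_ld_buddies, flip_prob=0.05)]
            if n_ld_buddies
            else []
        )
        sim_cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_variants=n_variants,
            maf_range=(maf, maf),
            seed=(seed + 7919 * rep) % (2**31 - 1),
            effects=[EffectSpec(planted, base_effect=0.0, age_slope=slope)],
            ld_blocks=ld,
        )
        res = stratified_diff_study(sim_cfg, k=k, pair=("Q1", f"Q{k}"), clump=True)
        row = res.diff_table.set_index("SNP")
        if planted in row.index and row.loc[planted, "TIER"] == "genome-wide":
            n_sig += 1
            lead_of = {m: l.lead_id for l in res.loci for m in l.members}
            if lead_of.get(planted) == planted:
                n_lead_when_sig += 1
    return {
        "n_replicates": n_replicates,
        "age_slope": slope,
        "noncentrality_target": target,
        "n_genome_wide": n_sig,
        "power": n_sig / n_replicates,
        "n_lead_when_significant": n_lead_when_sig,
        "lead_fraction_when_significant": (n_lead_when_sig / n_sig) if n_sig else float("nan"),
    }
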
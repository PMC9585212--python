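"""End-to-end driver: simulate -> qc -> stratify -> GWAS -> correlation ->
differential -> clump -> report, with per-stage logging and seeding.

Every artifact is written under ``out_dir``; outputs are deterministic
given the config seed (each stochastic stage derives a named sub-seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import CovariateSpec, run_stratified_gwas
from .clump import greedy_clump, loci_to_frames, manhattan_table, qq_table
from .config import PipelineConfig, stage_rng
from .datatypes import GenotypeMatrix, PhenotypeTable
from .differential import (
    CorrelationReport,
    pairwise_beta_correlation,
    run_differential,
    write_diff_table,
)
from .errors import StratGwasError
from .io import write_summary_stats
from .qc import QCReport, filter_snps
from .simulate import (
    SimulationConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype,
    truth_table,
    write_dataset,
)
from .strata import StratumAssignment, assign_age_quartiles

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory view of everything a run produced."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    qc_report: QCReport
    strata: StratumAssignment
    stratum_stats: dict
    correlation: CorrelationReport
    pair: tuple
    diff_table: pd.DataFrame
    loci: list
    truth: pd.DataFrame | None = None
    paths: dict = field(default_factory=dict)


def _stage(name):
    logger.info("stage %s: start", name)
    return name


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    genotypes: GenotypeMatrix | None = None,
    phenotypes: PhenotypeTable | None = None,
    write_plots: bool = False,
) -> PipelineResult:
    """Execute the full age-stratified differential GWAS.

    If ``genotypes``/``phenotypes`` are not supplied, a synthetic cohort is
    generated from ``config.simulation``. Raises the failing stage's error
    prefixed with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    truth = None
    stage = "simulate"
    try:
        if genotypes is None or phenotypes is None:
            sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
            genotypes = simulate_genotypes(sim_cfg, stage_rng(config.seed, "simulate_genotypes"))
            cov = simulate_covariates(sim_cfg, stage_rng(config.seed, "simulate_covariates"))
            y = simulate_phenotype(
                genotypes, cov, sim_cfg, stage_rng(config.seed, "simulate_phenotype")
            )
            cov = cov.copy()
            cov["pheno"] = y
            cov_names = [c for c in config.covariates if c in cov.columns]
            phenotypes = PhenotypeTable(cov, "pheno", cov_names)
            truth = truth_table(sim_cfg)
            paths.update(write_dataset(genotypes, phenotypes, truth, out / "simulated"))
            logger.info(
                "simulate: %d individuals, %d variants, %d causal effect(s)",
                genotypes.n_individuals, genotypes.n_variants, len(sim_cfg.effects),
            )

        stage = "qc"
        genotypes, qc_report = filter_snps(genotypes, config.qc)
        logger.info(
            "qc: %d variants in, %d retained, %d removed",
            qc_report.n_in, qc_report.n_out, qc_report.n_removed,
        )
        paths["qc_report"] = out / "qc_report.tsv"
        qc_report.table.to_csv(paths["qc_report"], sep="\t", index=False)

        stage = "stratify"
        strata = assign_age_quartiles(
            phenotypes.data["age"].to_numpy(), list(phenotypes.ids), k=config.n_strata
        )
        logger.info("stratify: %s", strata.summary.to_dict("records"))
        paths["strata"] = out / "strata.tsv"
        strata.assignments.to_frame().reset_index().to_csv(paths["strata"], sep="\t", index=False)

        stage = "gwas"
        spec = CovariateSpec(list(config.covariates))
        stratum_stats = run_stratified_gwas(genotypes, phenotypes, strata, spec)
        for label, frame in stratum_stats.items():
            p = out / f"{phenotypes.phenotype_name}.{label}.assoc.tsv"
            write_summary_stats(frame, p)
            paths[f"assoc_{label}"] = p
            logger.info("gwas %s: %d records", label, len(frame))

        stage = "correlation"
        correlation = pairwise_beta_correlation(stratum_stats, strata.labels)
        paths["correlation"] = out / "correlation.tsv"
        correlation.pairs.to_csv(paths["correlation"], sep="\t", index=False)
        logger.info("correlation: selected pair %s", correlation.selected)

        stage = "diff"
        if config.stratum_pair == "auto":
            pair = correlation.selected
        else:
            pair = tuple(config.stratum_pair)
        r = correlation.r_for(*pair)
        diff_table = run_differential(
            stratum_stats[pair[0]],
            stratum_stats[pair[1]],
            r_override=r,
            genome_wide_p=config.genome_wide_p,
            suggestive_p=config.suggestive_p,
        )
        paths["diff"] = out / f"diff.{pair[0]}_{pair[1]}.tsv"
        write_diff_table(diff_table, paths["diff"])
        n_gw = int((diff_table["TIER"] == "genome-wide").sum())
        logger.info("diff %s vs %s: %d variants, %d genome-wide", *pair, len(diff_table), n_gw)

        stage = "clump"
        loci = greedy_clump(
            diff_table,
            genotypes,
            p_threshold=config.clump.p_threshold,
            r2_threshold=config.clump.r2_threshold,
            merge_window=config.clump.merge_window,
        )
        lead_frame, member_frame = loci_to_frames(loci)
        paths["loci"] = out / "loci.tsv"
        paths["locus_members"] = out / "locus_members.tsv"
        lead_frame.to_csv(paths["loci"], sep="\t", index=False)
        member_frame.to_csv(paths["locus_members"], sep="\t", index=False)
        logger.info("clump: %d locus/loci", len(loci))

        stage = "report"
        mh = manhattan_table(diff_table, "P_DIFF", (config.genome_wide_p, config.suggestive_p))
        qq, lam = qq_table(diff_table["P_DIFF"].to_numpy())
        paths["manhattan"] = out / "manhattan.tsv"
        paths["qq"] = out / "qq.tsv"
        mh.to_csv(paths["manhattan"], sep="\t", index=False)
        qq.to_csv(paths["qq"], sep="\t", index=False)
        (out / "lambda.txt").write_text(f"{lam:.6f}\n")
        logger.info("report: genomic inflation lambda = %.4f", lam)
        if write_plots:
            from .clump import manhattan_plot, qq_plot

            manhattan_plot(mh, out / "manhattan.png")
            qq_plot(qq, lam, out / "qq.png")
    except StratGwasError as exc:
        raise StratGwasError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return PipelineResult(
        genotypes=genotypes,
        phenotypes=phenotypes,
        qc_report=qc_report,
        strata=strata,
        stratum_stats=stratum_stats,
        correlation=correlation,
        pair=pair,
        diff_table=diff_table,
        loci=loci,
        truth=truth,
        paths=paths,
    )
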
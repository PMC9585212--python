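"""Per-stratum, per-SNP covariate-adjusted linear association (the GWAS engine).

Each variant is tested with ordinary least squares on the complete cases
for that variant: design ``[1, dosage, covariates]``, two-sided p from the
t distribution with the residual degrees of freedom. Within a stratum,
age remains a covariate (age varies inside each quartile and is adjusted
for again there).

Two computational paths produce identical results:

* a per-variant fit (:func:`snp_association`) via least squares, used
  whenever a variant has missing calls so its complete-case set differs;
* a vectorised batch path for fully observed variants that residualises
  the phenotype and all dosage columns against the covariates once
  (Frisch-Waugh-Lovell) and reads every beta/SE off dot products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_COVARIATES
from .datatypes import MISSING, GenotypeMatrix, PhenotypeTable
from .errors import (
    CollinearityError,
    DomainError,
    InsufficientDataError,
    SchemaError,
)
from .strata import StratumAssignment

NORMAL_DF_CUTOFF = 10_000  # above this the t distribution is treated as normal


@dataclass
class CovariateSpec:
    """Ordered covariate names entering the design after the dosage column."""

    names: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError(f"duplicate covariate names: {self.names}")

    def validate_against(self, table: PhenotypeTable) -> None:
        absent = [c for c in self.names if c not in table.data.columns]
        if absent:
            raise SchemaError(
                f"covariates {absent} not in phenotype table; "
                f"available: {list(table.data.columns)}"
            )


@dataclass
class AssocRecord:
    """One variant's association result within one stratum."""

    variant_id: str
    stratum: str
    n: int
    beta: float
    se: float
    stat: float
    p: float

    @property
    def flagged(self) -> bool:
        """True for variants that could not be tested (e.g. monomorphic)."""
        return not np.isfinite(self.p)


# ----------------------------------------------------------------------
def fit_ols(y: np.ndarray, X: np.ndarray, column_names=None):
    """OLS fit returning (coefficients, standard errors, residual df).

    ``X`` must include the intercept column. Standard errors come from
    sigma^2 * diag((X'X)^-1) with sigma^2 = RSS / (n - p). A rank-deficient
    design raises :class:`CollinearityError` naming the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if column_names is None:
        column_names = [f"x{j}" for j in range(p)]
    if n <= p:
        raise InsufficientDataError(f"{n} observations cannot identify {p} coefficients")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.max() > 0 else 0.0
    dependent = diag <= tol
    if dependent.any():
        bad = [column_names[j] for j in np.flatnonzero(dependent)]
        raise CollinearityError(f"design is rank deficient; dependent column(s): {bad}")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df
    rinv = np.linalg.solve(r, np.eye(p))
    se = np.sqrt(np.maximum(sigma2 * np.sum(rinv * rinv, axis=1), 0.0))
    return coef, se, df


def pvalue_from_beta_se(beta: float, se: float, df: float = np.inf) -> float:
    """Two-sided p for beta/se against the t distribution with ``df``.

    ``df`` of inf (or >= 10^4, where the two are numerically identical)
    uses the standard normal. Computed through the survival function so
    extreme statistics keep full precision.
    """
    if se <= 0:
        raise DomainError(f"standard error must be > 0, got {se}")
    if not df > 0:
        raise DomainError(f"degrees of freedom must be > 0, got {df}")
    z = abs(beta / se)
    if np.isinf(df) or df >= NORMAL_DF_CUTOFF:
        p = 2.0 * stats.norm.sf(z)
    else:
        p = 2.0 * stats.t.sf(z, df)
    return float(min(p, 1.0))


def snp_association(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray,
    variant_id: str = "",
    stratum: str = "",
    covariate_names=None,
) -> AssocRecord:
    """Test one variant: complete-case OLS of phenotype on dosage + covariates.

    Rows with a missing dosage, phenotype or covariate are excluded for
    this variant only. A variant monomorphic after complete-case filtering
    is returned flagged (beta/se/p = NaN) rather than raised, so stratum
    outputs stay row-aligned.
    """
    g = np.asarray(dosages, dtype=float)
    g[np.asarray(dosages) == MISSING] = np.nan
    y = np.asarray(phenotype, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = np.isfinite(g) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    g, y, C = g[ok], y[ok], C[ok]
    n = int(ok.sum())
    if n == 0 or np.all(g == g[0]):
        return AssocRecord(variant_id, stratum, n, np.nan, np.nan, np.nan, np.nan)
    X = np.column_stack([np.ones(n), g, C])
    names = ["intercept", "dosage"] + list(
        covariate_names or [f"cov{j}" for j in range(C.shape[1])]
    )
    coef, se, df = fit_ols(y, X, names)
    beta, beta_se = float(coef[1]), float(se[1])
    if beta_se > 0:
        stat = beta / beta_se
        p = pvalue_from_beta_se(beta, beta_se, df)
    else:  # perfect fit: no sampling noise to test against
        stat, p = np.nan, np.nan
    return AssocRecord(variant_id, stratum, n, beta, beta_se, stat, p)


# ----------------------------------------------------------------------
def _batch_assoc(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Vectorised OLS for fully observed dosage columns (Frisch-Waugh-Lovell).

    Residualises y and every column of G against [1, C] once, then each
    variant's beta, SE and residual df follow from dot products. Equivalent
    to fitting [1, g, C] per variant (property-tested).
    """
    n = len(y)
    X = np.column_stack([np.ones(n), C])
    p_cov = X.shape[1]
    XtX = X.T @ X
    coef_y = np.linalg.solve(XtX, X.T @ y)
    y_t = y - X @ coef_y
    coef_G = np.linalg.solve(XtX, X.T @ G)
    G_t = G - X @ coef_G
    gg = np.einsum("ij,ij->j", G_t, G_t)
    gy = G_t.T @ y_t
    df = n - (p_cov + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = np.maximum(float(y_t @ y_t) - beta**2 * gg, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
    mono = gg <= n * np.finfo(float).eps * 4
    beta[mono] = np.nan
    se[mono] = np.nan
    return beta, se, df


def run_stratified_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    strata: StratumAssignment,
    covariates: CovariateSpec | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-stratum GWAS: one summary-stats frame per stratum.

    Returns a dict ``{stratum label: DataFrame}`` in the summary-stats
    dialect (CHR SNP BP A1 A2 NMISS BETA SE STAT P), one row per variant
    per stratum, row-aligned across strata. Flagged (untestable) variants
    carry NaN statistics.
    """
    spec = covariates or CovariateSpec()
    spec.validate_against(phenotypes)
    id_to_row = {iid: i for i, iid in enumerate(genotypes.samples)}
    missing_ids = [iid for iid in phenotypes.ids if iid not in id_to_row]
    if missing_ids:
        raise SchemaError(
            f"{len(missing_ids)} phenotype ids absent from genotypes, e.g. {missing_ids[:3]}"
        )
    pheno_complete = ~phenotypes.missing_mask
    y_all = phenotypes.phenotype()
    C_all = phenotypes.data[spec.names].to_numpy(dtype=float)
    pheno_rows = np.array([id_to_row[iid] for iid in phenotypes.ids])

    results: dict[str, pd.DataFrame] = {}
    meta = pd.DataFrame(
        {
            "CHR": [v.chrom for v in genotypes.variants],
            "SNP": [v.id for v in genotypes.variants],
            "BP": [v.pos for v in genotypes.variants],
            "A1": [v.a1 for v in genotypes.variants],
            "A2": [v.a2 for v in genotypes.variants],
        }
    )
    for label in strata.labels:
        in_stratum = (strata.assignments.reindex(phenotypes.ids).to_numpy() == label)
        use = in_stratum & pheno_complete
        n_s = int(use.sum())
        if n_s < len(spec.names) + 4:
            raise InsufficientDataError(
                f"stratum {label} has {n_s} complete cases for a design with "
                f"{len(spec.names) + 2} columns"
            )
        rows = pheno_rows[use]
        y = y_all[use]
        C = C_all[use]
        G_int = genotypes.dosages[rows, :]
        has_missing = (G_int == MISSING).any(axis=0)

        beta = np.full(genotypes.n_variants, np.nan)
        se = np.full(genotypes.n_variants, np.nan)
        nmiss = np.full(genotypes.n_variants, n_s, dtype=int)
        pvals = np.full(genotypes.n_variants, np.nan)
        stat = np.full(genotypes.n_variants, np.nan)

        clean = np.flatnonzero(~has_missing)
        if clean.size:
            b, s, df = _batch_assoc(G_int[:, clean].astype(float), y, C)
            beta[clean], se[clean] = b, s
            ok = np.isfinite(b) & (s > 0)
            stat[clean[ok]] = b[ok] / s[ok]
            if df >= NORMAL_DF_CUTOFF:
                pvals[clean[ok]] = 2.0 * stats.norm.sf(np.abs(stat[clean[ok]]))
            else:
                pvals[clean[ok]] = 2.0 * stats.t.sf(np.abs(stat[clean[ok]]), df)
        for j in np.flatnonzero(has_missing):
            rec = snp_association(
                G_int[:, j], y, C, genotypes.variants[j].id, label, spec.names
            )
            beta[j], se[j], stat[j], pvals[j], nmiss[j] = rec.beta, rec.se, rec.stat, rec.p, rec.n

        out = meta.copy()
        out["NMISS"] = nmiss
        out["BETA"] = beta
        out["SE"] = se
        out["STAT"] = stat
        out["P"] = pvals
        results[label] = out
    return results
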
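"""The differential-effect test between two age strata.

Effect sizes estimated in two strata of one cohort are positively
correlated through shared environment and overlapping genetic signal, so
the naive two-sample z statistic over-estimates the null variance of the
difference. The test used here corrects the variance with the rank
correlation r of the two strata's effect-size vectors:

    t = (b1 - b2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2)

with a single scalar r (the signed Spearman correlation of the betas over
all shared variants) applied to every variant, and a two-sided standard
normal reference for the p-value P_diff. At stratum sizes in the tens of
thousands the t and normal references are indistinguishable. The
least-correlated stratum pair is the one compared, since it carries the
most differential information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .config import GENOME_WIDE_P, SUGGESTIVE_P
from .errors import DomainError

logger = logging.getLogger(__name__)

DIFF_COLUMNS = [
    "CHR", "SNP", "BP", "A1", "A2",
    "BETA1", "SE1", "N1", "BETA2", "SE2", "N2",
    "R", "T", "P_DIFF", "TIER",
]


@dataclass
class CorrelationReport:
    """Spearman correlation of effect sizes for every stratum pair."""

    pairs: pd.DataFrame  # columns: stratum1, stratum2, r, n_variants, selected
    selected: tuple[str, str]

    def r_for(self, s1: str, s2: str) -> float:
        key = tuple(sorted((s1, s2)))
        for _, row in self.pairs.iterrows():
            if tuple(sorted((row["stratum1"], row["stratum2"]))) == key:
                return float(row["r"])
        raise KeyError(f"no pair {s1}/{s2} in report")


def spearman_correlation(x, y) -> float:
    """Signed Spearman rank correlation (Pearson correlation of mean ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise DomainError(f"need >= 3 observations, got {len(x)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DomainError("inputs must not contain missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def pairwise_beta_correlation(
    stats_by_stratum: dict[str, pd.DataFrame], stratum_order: list[str] | None = None
) -> CorrelationReport:
    """Spearman r between every stratum pair's beta vectors; select the minimum.

    r is computed over the intersection of variants with finite betas in
    both strata. Ties at the minimum go to the pair with the widest age gap
    (largest separation in the stratum order, youngest first), then to the
    lexicographically first pair.
    """
    labels = stratum_order or sorted(stats_by_stratum)
    if len(labels) < 2:
        raise DomainError("need at least two strata to correlate")
    betas = {
        lab: stats_by_stratum[lab].set_index("SNP")["BETA"].dropna() for lab in labels
    }
    rows = []
    for s1, s2 in combinations(labels, 2):
        shared = betas[s1].index.intersection(betas[s2].index)
        if len(shared) < 3:
            raise DomainError(f"strata {s1}/{s2} share only {len(shared)} variants with betas")
        r = spearman_correlation(betas[s1].loc[shared].to_numpy(), betas[s2].loc[shared].to_numpy())
        rows.append({"stratum1": s1, "stratum2": s2, "r": r, "n_variants": len(shared)})
    df = pd.DataFrame(rows)
    gap = df.apply(
        lambda row: abs(labels.index(row["stratum2"]) - labels.index(row["stratum1"])), axis=1
    )
    order = df.assign(gap=gap).sort_values(
        by=["r", "gap", "stratum1", "stratum2"], ascending=[True, False, True, True]
    )
    best = order.iloc[0]
    selected = (best["stratum1"], best["stratum2"])
    df["selected"] = [
        (row["stratum1"], row["stratum2"]) == selected for _, row in df.iterrows()
    ]
    return CorrelationReport(df, selected)


def differential_t(b1: float, se1: float, b2: float, se2: float, r: float):
    """Correlation-corrected t statistic for the difference of two betas.

    Vectorised over b1/se1/b2/se2; r is a scalar in (-1, 1].
    """
    se1 = np.asarray(se1, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise DomainError("standard errors must be > 0")
    if not (-1 < r <= 1):
        raise DomainError(f"correlation r must be in (-1, 1], got {r}")
    var = se1**2 + se2**2 - 2.0 * r * se1 * se2
    if np.any(var <= 0):
        raise DomainError(
            "degenerate variance: se1^2 + se2^2 - 2 r se1 se2 <= 0 (r -> 1 with se1 = se2)"
        )
    t = (np.asarray(b1, dtype=float) - np.asarray(b2, dtype=float)) / np.sqrt(var)
    return float(t) if t.ndim == 0 else t


def differential_pvalue(t):
    """Two-sided standard-normal p for the differential statistic.

    Uses the survival function, numerically stable down to p ~ 1e-300.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DomainError("t must be finite")
    p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def assign_tier(p_diff, genome_wide_p: float = GENOME_WIDE_P, suggestive_p: float = SUGGESTIVE_P):
    p = np.asarray(p_diff, dtype=float)
    tier = np.where(p < genome_wide_p, "genome-wide", np.where(p < suggestive_p, "suggestive", "none"))
    return tier if tier.ndim else str(tier)


def harmonize(group1: pd.DataFrame, group2: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Align group 2's effect alleles to group 1's over shared variants.

    Exact allele match keeps the beta; swapped a1/a2 flips its sign;
    anything else excludes the variant (counted and logged). Returns the
    merged frame and the number of excluded variants.
    """
    merged = group1.merge(group2, on="SNP", suffixes=("_1", "_2"))
    same = (merged["A1_1"] == merged["A1_2"]) & (merged["A2_1"] == merged["A2_2"])
    swapped = (merged["A1_1"] == merged["A2_2"]) & (merged["A2_1"] == merged["A1_2"])
    merged.loc[swapped, "BETA_2"] = -merged.loc[swapped, "BETA_2"]
    keep = same | swapped
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("excluded %d variant(s) with unharmonizable alleles", n_excluded)
    return merged[keep].copy(), n_excluded


def run_differential(
    stats_group1: pd.DataFrame,
    stats_group2: pd.DataFrame,
    r_override: float | None = None,
    genome_wide_p: float = GENOME_WIDE_P,
    suggestive_p: float = SUGGESTIVE_P,
) -> pd.DataFrame:
    """Differential test for every variant shared by two strata's summary stats.

    Alleles are harmonized first; variants lacking a finite beta/SE in
    either stratum are dropped. r defaults to the Spearman correlation of
    the two (harmonized) beta vectors and may be overridden, e.g. with a
    correlation estimated on a larger variant set.

    Returns the diff table (columns :data:`DIFF_COLUMNS`) sorted by
    ascending P_diff.
    """
    merged, _ = harmonize(stats_group1, stats_group2)
    ok = (
        np.isfinite(merged["BETA_1"]) & np.isfinite(merged["SE_1"]) & (merged["SE_1"] > 0)
        & np.isfinite(merged["BETA_2"]) & np.isfinite(merged["SE_2"]) & (merged["SE_2"] > 0)
    )
    merged = merged[ok]
    if merged.empty:
        raise DomainError("no shared variants with finite betas in both strata")
    b1 = merged["BETA_1"].to_numpy()
    b2 = merged["BETA_2"].to_numpy()
    se1 = merged["SE_1"].to_numpy()
    se2 = merged["SE_2"].to_numpy()
    if r_override is not None:
        r = float(r_override)
    elif len(merged) >= 3 and not (np.all(b1 == b1[0]) or np.all(b2 == b2[0])):
        r = spearman_correlation(b1, b2)
    else:
        r = 0.0
    # var can hit zero only as r -> 1 with se1 = se2 (e.g. comparing a
    # stratum with itself); a zero beta difference then has t = 0 by
    # continuity, while a nonzero difference is genuinely degenerate.
    var = se1**2 + se2**2 - 2.0 * r * se1 * se2
    zero_var = var <= 0
    if np.any(zero_var & (b1 != b2)):
        raise DomainError(
            "degenerate variance with unequal betas: se1^2 + se2^2 - 2 r se1 se2 <= 0"
        )
    t = np.zeros(len(merged))
    t[~zero_var] = (b1[~zero_var] - b2[~zero_var]) / np.sqrt(var[~zero_var])
    p_diff = differential_pvalue(t)
    out = pd.DataFrame(
        {
            "CHR": merged["CHR_1"].to_numpy(),
            "SNP": merged["SNP"].to_numpy(),
            "BP": merged["BP_1"].to_numpy(),
            "A1": merged["A1_1"].to_numpy(),
            "A2": merged["A2_1"].to_numpy(),
            "BETA1": b1,
            "SE1": se1,
            "N1": merged["NMISS_1"].to_numpy(),
            "BETA2": b2,
            "SE2": se2,
            "N2": merged["NMISS_2"].to_numpy(),
            "R": r,
            "T": t,
            "P_DIFF": p_diff,
            "TIER": assign_tier(p_diff, genome_wide_p, suggestive_p),
        }
    )
    return out.sort_values(["P_DIFF", "SNP"], kind="mergesort").reset_index(drop=True)


def write_diff_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("BETA1", "SE1", "BETA2", "SE2", "R", "T", "P_DIFF"):
        out[col] = out[col].map(lambda x: "NA" if pd.isna(x) else f"{x:.6e}")
    out.to_csv(path, sep="\t", index=False)


def read_diff_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"CHR": str, "SNP": str, "A1": str, "A2": str, "TIER": str}
    )
    for col in ("BETA1", "SE1", "BETA2", "SE2", "R", "T", "P_DIFF"):
        df[col] = pd.to_numeric(df[col].replace("NA", np.nan))
    return df


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if not (0 < alpha <= 1):
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    if m < 1:
        raise DomainError(f"number of tests must be >= 1, got {m}")
    return alpha / m
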
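"""LD computation, greedy clumping of differential results, and plot tables.

Clumping proceeds in two stages:

1. among variants with P_diff below the significance threshold, iterate in
   ascending P_diff (ties broken by variant id): the best remaining variant
   becomes a lead and absorbs every remaining significant variant with
   r^2 >= ``r2_threshold`` to it;
2. leads on the same chromosome closer than ``merge_window`` base pairs are
   merged (transitively) into a single locus, keeping the smallest-P_diff
   lead, so surviving loci are separated by more than the window or sit on
   different chromosomes.

LD (r^2) is the squared Pearson correlation of dosages over pairwise
complete individuals, computed from the analysis genotypes themselves (an
external reference-panel VCF can be supplied instead of the analysis
matrix wherever a :class:`~stratgwas.datatypes.GenotypeMatrix` is accepted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GENOME_WIDE_P, SUGGESTIVE_P
from .datatypes import MISSING, GenotypeMatrix, chrom_sort_key
from .errors import DomainError

logger = logging.getLogger(__name__)


@dataclass
class Locus:
    """A clumped locus: a lead variant plus the members it recruited."""

    lead_id: str
    lead_p: float
    chrom: str
    start: int
    end: int
    members: dict = field(default_factory=dict)  # variant id -> r^2 to its recruiting lead

    @property
    def n_members(self) -> int:
        return len(self.members)


def ld_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Uses pairwise-complete individuals; requires >= 3 of them and both
    columns non-constant on that subset.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    ok = (d1 != MISSING) & (d2 != MISSING) & np.isfinite(d1) & np.isfinite(d2)
    x, y = d1[ok], d2[ok]
    if len(x) < 3:
        raise DomainError(f"need >= 3 shared non-missing individuals, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("LD undefined for a constant dosage column")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _ld_to_lead(G: np.ndarray, lead_col: int, other_cols: np.ndarray) -> np.ndarray:
    """r^2 of one lead column against many columns (vectorised when complete)."""
    lead = G[:, lead_col]
    if (G == MISSING).any():
        out = np.empty(len(other_cols))
        for i, j in enumerate(other_cols):
            try:
                out[i] = ld_r2(lead, G[:, j])
            except DomainError:
                out[i] = 0.0
        return out
    g = G[:, other_cols].astype(float)
    lead = lead.astype(float)
    lc = lead - lead.mean()
    gc = g - g.mean(axis=0)
    denom = np.sqrt((lc @ lc) * np.einsum("ij,ij->j", gc, gc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (gc.T @ lc) / denom
    r[~np.isfinite(r)] = 0.0
    return r * r


def greedy_clump(
    diff_table: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.1,
    merge_window: int = 250_000,
) -> list[Locus]:
    """Clump a differential-results table into lead loci (see module docstring).

    Variants present in the diff table but absent from the genotype matrix
    are excluded with a logged count. Returns loci sorted by lead P_diff.
    """
    sig = diff_table[diff_table["P_DIFF"] < p_threshold].copy()
    known = set(genotypes.variant_ids)
    absent = [s for s in sig["SNP"] if s not in known]
    if absent:
        logger.warning("excluded %d significant variant(s) absent from genotypes", len(absent))
        sig = sig[sig["SNP"].isin(known)]
    if sig.empty:
        return []
    sig = sig.sort_values(["P_DIFF", "SNP"], kind="mergesort")
    col_of = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    pos_of = {v.id: v.pos for v in genotypes.variants}
    chrom_of = {v.id: v.chrom for v in genotypes.variants}

    # stage 1: greedy absorption by LD
    remaining = list(sig["SNP"])
    p_of = dict(zip(sig["SNP"], sig["P_DIFF"]))
    loci: list[Locus] = []
    while remaining:
        lead = remaining.pop(0)
        members = {lead: 1.0}
        if remaining:
            cols = np.array([col_of[v] for v in remaining])
            r2 = _ld_to_lead(genotypes.dosages, col_of[lead], cols)
            absorbed = [v for v, q in zip(remaining, r2) if q >= r2_threshold]
            for v, q in zip(list(remaining), r2):
                if q >= r2_threshold:
                    members[v] = float(q)
            remaining = [v for v in remaining if v not in absorbed]
        positions = [pos_of[v] for v in members]
        loci.append(
            Locus(
                lead_id=lead,
                lead_p=float(p_of[lead]),
                chrom=chrom_of[lead],
                start=min(positions),
                end=max(positions),
                members=members,
            )
        )

    # stage 2: transitively merge leads within merge_window on one chromosome
    by_chrom: dict[str, list[Locus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    merged: list[Locus] = []
    for chrom, chrom_loci in by_chrom.items():
        chrom_loci.sort(key=lambda l: pos_of[l.lead_id])
        group = [chrom_loci[0]]
        for loc in chrom_loci[1:]:
            if pos_of[loc.lead_id] - pos_of[group[-1].lead_id] <= merge_window:
                group.append(loc)
            else:
                merged.append(_merge_group(group, pos_of))
                group = [loc]
        merged.append(_merge_group(group, pos_of))
    merged.sort(key=lambda l: (l.lead_p, l.lead_id))
    return merged


def _merge_group(group: list[Locus], pos_of: dict) -> Locus:
    if len(group) == 1:
        return group[0]
    best = min(group, key=lambda l: (l.lead_p, l.lead_id))
    members: dict = {}
    for loc in group:
        members.update(loc.members)
    positions = [pos_of[v] for v in members]
    return Locus(
        lead_id=best.lead_id,
        lead_p=best.lead_p,
        chrom=best.chrom,
        start=min(positions),
        end=max(positions),
        members=members,
    )


def loci_to_frames(loci: list[Locus]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loci summary and per-member tables for the report writer."""
    lead_rows = [
        {
            "lead": l.lead_id,
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "n_members": l.n_members,
            "lead_p_diff": l.lead_p,
        }
        for l in loci
    ]
    member_rows = [
        {"lead": l.lead_id, "member": m, "r2_to_lead": q}
        for l in loci
        for m, q in sorted(l.members.items())
    ]
    return (
        pd.DataFrame(lead_rows, columns=["lead", "chrom", "start", "end", "n_members", "lead_p_diff"]),
        pd.DataFrame(member_rows, columns=["lead", "member", "r2_to_lead"]),
    )


# ----------------------------------------------------------------------
# Plot-ready tables
# ----------------------------------------------------------------------
def manhattan_table(
    results: pd.DataFrame,
    p_column: str = "P_DIFF",
    thresholds: tuple = (GENOME_WIDE_P, SUGGESTIVE_P),
) -> pd.DataFrame:
    """Rows (chrom, pos, cumulative pos, -log10 p) sorted for plotting.

    The cumulative coordinate concatenates chromosomes in sorted order and
    is strictly increasing. Threshold -log10 lines are attached as
    ``DataFrame.attrs['thresholds']``.
    """
    p = results[p_column].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError(f"{p_column} values must lie in (0, 1]")
    df = pd.DataFrame(
        {
            "chrom": results["CHR"].astype(str).to_numpy(),
            "pos": results["BP"].to_numpy(dtype=int),
            "neg_log10_p": -np.log10(p),
        }
    )
    df = df.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
    offset = 0
    cum = np.empty(len(df), dtype=np.int64)
    for chrom in df["chrom"].unique():
        idx = df.index[df["chrom"] == chrom]
        cum[idx] = df.loc[idx, "pos"].to_numpy() + offset
        offset = int(cum[idx].max()) + 1
    df.insert(2, "cum_pos", cum)
    df.attrs["thresholds"] = {f"{t:g}": float(-np.log10(t)) for t in thresholds}
    return df


def qq_table(p_values) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 p quantiles plus genomic-inflation lambda.

    Expected quantiles are i/(n+1); lambda is the median of the chi-square
    statistics implied by the p-values divided by the null chi-square(1)
    median (~0.4549).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DomainError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = len(obs)
    expected = np.arange(1, n + 1) / (n + 1.0)
    table = pd.DataFrame(
        {"expected_neg_log10_p": -np.log10(expected), "observed_neg_log10_p": -np.log10(obs)}
    )
    chisq = stats.chi2.isf(p, df=1)
    lam = float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))
    return table, lam


def manhattan_plot(table: pd.DataFrame, path) -> None:
    """Optional PNG Manhattan plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for i, chrom in enumerate(table["chrom"].unique()):
        sub = table[table["chrom"] == chrom]
        ax.scatter(sub["cum_pos"], sub["neg_log10_p"], s=4, color=f"C{i % 2}")
    for label, y in table.attrs.get("thresholds", {}).items():
        ax.axhline(y, color="red" if y > 7 else "blue", lw=0.8, ls="--", label=f"p = {label}")
    ax.set_xlabel("cumulative position (bp)")
    ax.set_ylabel("-log10 P_diff")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(table: pd.DataFrame, lam: float, path) -> None:
    """Optional PNG QQ plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(table["expected_neg_log10_p"], table["observed_neg_log10_p"], s=4)
    lim = max(table["expected_neg_log10_p"].max(), table["observed_neg_log10_p"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(f"lambda = {lam:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
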
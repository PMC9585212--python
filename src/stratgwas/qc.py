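"""Variant-level quality control: call rate, MAF, and the HWE exact test.

Removal rules use strict inequalities on the removal side: a variant is
dropped iff missing rate > max_missing_rate, MAF < min_maf, or HWE exact
p < min_hwe_p. QC is computed on the full cohort before stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import QCThresholds
from .datatypes import MISSING, GenotypeMatrix
from .errors import DomainError

__all__ = [
    "QCThresholds",
    "QCReport",
    "call_rate",
    "minor_allele_freq",
    "hwe_exact_test",
    "filter_snps",
]


@dataclass
class QCReport:
    """Per-variant QC metrics and pass/fail bookkeeping.

    ``table`` has one row per input variant with columns
    ``variant_id, missing_rate, maf, hwe_p, passed, reasons``
    (reasons is a comma-joined subset of {missing,maf,hwe}).
    """

    table: pd.DataFrame
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def call_rate(dosages: np.ndarray) -> float:
    """Fraction of entries that are missing (despite the PLINK-style name,
    the QC threshold is on the *missing* fraction)."""
    dosages = np.asarray(dosages)
    if dosages.size == 0:
        raise DomainError("cannot compute missing rate of an empty dosage column")
    return float(np.mean(dosages == MISSING))


def minor_allele_freq(dosages: np.ndarray) -> float:
    """MAF from non-missing dosages: min(p, 1-p) with p = sum(d) / (2 n)."""
    dosages = np.asarray(dosages)
    obs = dosages[dosages != MISSING]
    if obs.size == 0:
        raise DomainError("MAF undefined: all genotypes missing")
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def _het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given ``n`` genotyped individuals and ``n_minor`` copies of the minor
    allele, the heterozygote count under HWE is confined to values of the
    same parity as ``n_minor`` in ``[max(0, n_minor - n), min(n_minor,
    2n - n_minor)]`` with probability proportional to

        n! / (n_hom_minor! n_het! n_hom_major!) * 2^n_het

    Returns the support and normalised log-probabilities.
    """
    lo = max(0, n_minor - n)
    hi = min(n_minor, 2 * n - n_minor)
    het = np.arange(lo, hi + 1, 2) if (lo % 2) == (n_minor % 2) else np.arange(lo + 1, hi + 1, 2)
    hom_minor = (n_minor - het) // 2
    hom_major = n - het - hom_minor
    logw = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(het + 1)
        - gammaln(hom_major + 1)
        + het * np.log(2.0)
    )
    return het, logw - logsumexp(logw)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE test p-value for genotype counts.

    The p-value sums the probabilities of all heterozygote counts (with the
    allele counts fixed) whose conditional probability does not exceed the
    observed count's, the standard exact (not mid-p) SNP-HWE convention.
    Returns a value in (0, 1]; a monomorphic site has a single possible
    configuration and p = 1.
    """
    counts = (int(n_aa), int(n_ab), int(n_bb))
    if any(c < 0 for c in counts):
        raise DomainError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n < 1:
        raise DomainError("need at least one genotyped individual for the HWE test")
    n_aa, n_ab, n_bb = counts
    allele_a = 2 * n_aa + n_ab
    n_minor = min(allele_a, 2 * n - allele_a)
    het_obs = n_ab
    het, logp = _het_log_probs(n, n_minor)
    probs = np.exp(logp)
    obs_idx = np.flatnonzero(het == het_obs)
    if obs_idx.size == 0:  # cannot happen for consistent counts
        raise DomainError(f"inconsistent genotype counts {counts}")
    p_obs = probs[obs_idx[0]]
    # small relative tolerance so equal-probability tables tie despite rounding
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _hwe_from_column(dosages: np.ndarray) -> float:
    obs = dosages[dosages != MISSING]
    n_bb = int(np.sum(obs == 0))
    n_ab = int(np.sum(obs == 1))
    n_aa = int(np.sum(obs == 2))
    return hwe_exact_test(n_aa, n_ab, n_bb)


# ----------------------------------------------------------------------
def filter_snps(
    matrix: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three exclusion rules and return survivors plus a report.

    A variant is removed iff missing rate > ``max_missing_rate`` OR
    maf < ``min_maf`` OR HWE exact p < ``min_hwe_p``. Variants whose MAF is
    undefined (all calls missing) fail both the missing and maf rules.
    Survivor order is preserved.
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    keep: list[str] = []
    for j, v in enumerate(matrix.variants):
        col = matrix.dosages[:, j]
        miss = call_rate(col)
        try:
            maf = minor_allele_freq(col)
            hwe_p = _hwe_from_column(col)
        except DomainError:
            maf, hwe_p = np.nan, np.nan
        reasons = []
        if miss > thresholds.max_missing_rate:
            reasons.append("missing")
        if np.isnan(maf) or maf < thresholds.min_maf:
            reasons.append("maf")
        if not np.isnan(hwe_p) and hwe_p < thresholds.min_hwe_p:
            reasons.append("hwe")
        passed = not reasons
        if passed:
            keep.append(v.id)
        rows.append(
            {
                "variant_id": v.id,
                "missing_rate": miss,
                "maf": maf,
                "hwe_p": hwe_p,
                "passed": passed,
                "reasons": ",".join(reasons),
            }
        )
    report = QCReport(table=pd.DataFrame(rows), n_in=matrix.n_variants, n_out=len(keep))
    return matrix.subset_variants(keep), report
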
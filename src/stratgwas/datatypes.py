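"""Core in-memory containers: variants, genotype matrices, phenotype tables.

Genotypes are additive hard-call dosages (copies of the effect allele ``a1``,
coded 0/1/2) stored as an ``int8`` matrix with ``-1`` marking missing calls.
Phenotype/covariate data live in a pandas DataFrame with one row per
individual; rows with a missing phenotype or covariate are *flagged* for
complete-case exclusion rather than dropped, so record counts stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

MISSING = -1  # sentinel for a missing hard call in the dosage matrix


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing numeric chromosomes first in numeric order.

    Labels are kept as strings throughout (no "chr" normalisation); this key
    only controls ordering: 1..22 numerically, then X, Y, MT, then anything
    else lexicographically.
    """
    c = str(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c in special:
        return (0, special[c], "")
    return (1, 0, c)


@dataclass(frozen=True)
class VariantInfo:
    """A biallelic variant. ``a1`` is the effect allele (ALT in VCF), ``a2`` the other."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ConfigError(f"variant {self.id}: position must be >= 1 (got {self.pos})")
        if self.a1 == self.a2:
            raise ConfigError(f"variant {self.id}: alleles must differ (a1 == a2 == {self.a1!r})")


class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with per-variant metadata.

    Parameters
    ----------
    variants
        Variant metadata, one entry per dosage column.
    dosages
        ``(n_individuals, n_variants)`` integer array with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    samples
        Individual identifiers, one per row.
    sort
        If True (default) the variants are sorted by ``(chrom, pos)``,
        keeping rows aligned.
    """

    def __init__(
        self,
        variants: Sequence[VariantInfo],
        dosages: np.ndarray,
        samples: Sequence[str],
        sort: bool = True,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ConfigError("dosages must be a 2-D (individuals x variants) array")
        if dosages.shape[1] != len(variants):
            raise ConfigError(
                f"{len(variants)} variants but dosage matrix has {dosages.shape[1]} columns"
            )
        if dosages.shape[0] != len(samples):
            raise ConfigError(
                f"{len(samples)} samples but dosage matrix has {dosages.shape[0]} rows"
            )
        valid = (dosages >= 0) & (dosages <= 2) | (dosages == MISSING)
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ConfigError(
                f"dosage entry at (sample {bad[0]}, variant {bad[1]}) is "
                f"{dosages[bad[0], bad[1]]}; must be 0, 1, 2 or missing ({MISSING})"
            )
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ConfigError(f"duplicate variant ids: {list(dup[dup > 1].index[:5])}")
        self.variants = list(variants)
        self.dosages = dosages
        self.samples = list(samples)
        if sort:
            self._sort_by_position()

    def _sort_by_position(self) -> None:
        order = sorted(
            range(len(self.variants)),
            key=lambda i: (chrom_sort_key(self.variants[i].chrom), self.variants[i].pos),
        )
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[i] for i in order]
            self.dosages = self.dosages[:, order]

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant id."""
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None
        return self.dosages[:, j]

    def subset_variants(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep = set(keep)
        idx = [j for j, v in enumerate(self.variants) if v.id in keep]
        return GenotypeMatrix(
            [self.variants[j] for j in idx], self.dosages[:, idx], self.samples, sort=False
        )

    def subset_individuals(self, row_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants,
            self.dosages[row_idx, :],
            [self.samples[i] for i in np.atleast_1d(row_idx)],
            sort=False,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.dosages, other.dosages)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_variants} variants)"


@dataclass
class PhenotypeTable:
    """Per-individual phenotype and covariates.

    ``data`` has one row per individual with an ``IID`` column plus the
    phenotype and covariate columns. ``missing_mask`` flags rows that have a
    missing phenotype or any requested covariate; they are excluded
    complete-case by the association engine but never silently dropped here.
    """

    data: pd.DataFrame
    phenotype_name: str
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "IID" not in self.data.columns:
            raise SchemaError(
                f"phenotype table needs an IID column; has {list(self.data.columns)}"
            )
        if self.data["IID"].duplicated().any():
            dups = self.data.loc[self.data["IID"].duplicated(), "IID"].tolist()[:5]
            raise SchemaError(f"duplicated individual ids: {dups}")
        needed = [self.phenotype_name, *self.covariate_names]
        missing_cols = [c for c in needed if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(
                f"missing column(s) {missing_cols}; available: {list(self.data.columns)}"
            )

    @property
    def ids(self) -> pd.Series:
        return self.data["IID"]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> np.ndarray:
        """True where the phenotype or any covariate is missing (complete-case flag)."""
        cols = [self.phenotype_name, *self.covariate_names]
        return self.data[cols].isna().any(axis=1).to_numpy()

    def phenotype(self) -> np.ndarray:
        return self.data[self.phenotype_name].to_numpy(dtype=float)

    def covariates(self) -> np.ndarray:
        """Covariate block as a float matrix in declared column order."""
        if not self.covariate_names:
            return np.empty((self.n, 0))
        return self.data[self.covariate_names].to_numpy(dtype=float)
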
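"""Readers and writers for the pipeline's on-disk formats.

Formats
-------
* Genotypes: VCF v4.x with GT fields only (hard calls). Reading goes
  through :mod:`cyvcf2`; multi-allelic records are rejected (split them
  upstream with ``bcftools norm``). Writing emits minimal VCF v4.2.
* Phenotypes/covariates: PLINK-style whitespace-delimited table with a
  header, ``FID IID`` (or a single ``IID``) first, ``NA`` = missing.
* Summary statistics: a TSV dialect of PLINK's ``.assoc.linear`` with
  columns ``CHR SNP BP A1 A2 NMISS BETA SE STAT P`` (tab-separated rather
  than space-aligned so parsing is loss-free).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PhenotypeTable, VariantInfo
from .errors import ParseError, SchemaError, UnsupportedRecordError

SUMMARY_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "NMISS", "BETA", "SE", "STAT", "P"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read hard-call genotypes from a VCF into a :class:`GenotypeMatrix`.

    Dosage counts copies of the ALT allele, so ``a1`` = ALT and ``a2`` = REF.
    ``./.`` becomes a missing entry. Variants are sorted by (chrom, pos).
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises plain Exception on bad headers
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise UnsupportedRecordError(
                f"{path}: record {i} ({rec.CHROM}:{rec.POS}) is multi-allelic "
                f"(ALT={rec.ALT}); split with 'bcftools norm -m-' first"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantInfo(id=vid, chrom=str(rec.CHROM), pos=int(rec.POS), a1=rec.ALT[0], a2=rec.REF)
        )
        # gts012=True: 0/1/2 = ALT copies, 3 = unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        columns.append(g)
    vcf.close()
    if columns:
        dosages = np.column_stack(columns)
    else:
        dosages = np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(variants, dosages, samples)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as minimal VCF v4.2 with GT hard calls."""
    path = Path(path)
    chroms = dict.fromkeys(v.chrom for v in matrix.variants)  # ordered unique
    lines = ["##fileformat=VCFv4.2", "##source=stratgwas"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if matrix.samples:  # a sample-less VCF must omit the FORMAT column
        header.append("FORMAT")
    lines.append("\t".join(header + list(matrix.samples)))
    for j, v in enumerate(matrix.variants):
        row = [v.chrom, str(v.pos), v.id, v.a2, v.a1, ".", ".", "."]
        if matrix.samples:
            row.append("GT")
            row += [_GT_STRINGS[int(d)] for d in matrix.dosages[:, j]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Phenotype / covariate table
# ----------------------------------------------------------------------
def read_pheno_covar(
    path: str | Path, phenotype_name: str, covariate_names: Sequence[str]
) -> PhenotypeTable:
    """Read a PLINK-style whitespace table into a :class:`PhenotypeTable`.

    Accepts either ``FID IID ...`` or a single ``IID`` id column first.
    Rows with a missing (NA) phenotype or requested covariate stay in the
    table and are flagged by :attr:`PhenotypeTable.missing_mask`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str}, na_values=["NA"])
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse whitespace table: {exc}") from exc
    if "IID" not in df.columns:
        raise SchemaError(f"{path}: no IID column; available: {list(df.columns)}")
    wanted = [phenotype_name, *covariate_names]
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing column(s) {absent}; available: {list(df.columns)}")
    return PhenotypeTable(df, phenotype_name, list(covariate_names))


def write_pheno_covar(table: PhenotypeTable, path: str | Path) -> None:
    """Write the table tab-delimited with FID=IID and NA for missing values."""
    df = table.data.copy()
    if "FID" not in df.columns:
        df.insert(0, "FID", df["IID"])
    cols = ["FID", "IID"] + [c for c in df.columns if c not in ("FID", "IID")]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ----------------------------------------------------------------------
# Summary statistics (.assoc.linear TSV dialect)
# ----------------------------------------------------------------------
def write_summary_stats(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-variant association records as the summary-stats TSV.

    ``records`` must carry the columns in :data:`SUMMARY_COLUMNS`. Real
    values are written in scientific notation with 6 significant digits so
    a round trip preserves them to printed precision.
    """
    absent = [c for c in SUMMARY_COLUMNS if c not in records.columns]
    if absent:
        raise SchemaError(f"summary-stats frame missing column(s) {absent}")
    out = records[SUMMARY_COLUMNS].copy()
    for col in ("BETA", "SE", "STAT", "P"):
        out[col] = out[col].map(lambda x: "NA" if pd.isna(x) else f"{x:.6e}")
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-stats TSV, validating schema and numeric fields."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str, "A1": str, "A2": str})
    unknown = [c for c in df.columns if c not in SUMMARY_COLUMNS]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}; expected {SUMMARY_COLUMNS}")
    absent = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing column(s) {absent}")
    for col in ("BETA", "SE", "STAT", "P"):
        raw = df[col].astype(str)
        numeric = pd.to_numeric(raw.replace("NA", np.nan), errors="coerce")
        bad = numeric.isna() & (raw != "NA") & (raw != "nan")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(f"{path}: non-numeric {col} at data row {row + 1}: {raw.iloc[row]!r}")
        df[col] = numeric
    df["BP"] = df["BP"].astype(int)
    df["NMISS"] = df["NMISS"].astype(int)
    return df
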
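"""Readers and writers for the tab-separated and VCF interchange formats.

TSV dialect (the bit-exact contract): tab separator, mandatory header
row, sample ids in the first column, ``.`` for missing values.  Genotypes
may alternatively be read from a VCF with per-sample ``DS`` dosages
(``GT`` hard calls are converted to 0/1/2 as a fallback).
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coloc import RegionalAssoc
from .matrices import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "read_dosage_tsv",
    "read_vcf",
    "read_expression_tsv",
    "read_covariates_tsv",
    "read_summary_stats",
    "write_eqtl_records",
]

logger = logging.getLogger(__name__)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    return df


def read_dosage_tsv(path: str | Path, annot_path: str | Path) -> GenotypeMatrix:
    """Sample-by-SNP dosage TSV plus a SNP annotation TSV.

    The annotation has columns (snp, chrom, pos, coded_allele,
    other_allele).  Non-numeric or out-of-range dosages are rejected with
    their row/column coordinates.
    """
    df = _read_matrix(path)
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric dosage at sample {row!r}, SNP {col!r}"
                ) from None
        raise
    vals = df.to_numpy()
    out_of_range = (vals < 0) | (vals > 2)
    if np.nansum(out_of_range):
        i, j = np.argwhere(np.nan_to_num(out_of_range.astype(float)) > 0)[0]
        raise ValueError(
            f"{path}: dosage {vals[i, j]} outside [0, 2] at sample "
            f"{df.index[i]!r}, SNP {df.columns[j]!r}"
        )
    meta = pd.read_csv(annot_path, sep="\t", index_col=0)
    meta = meta.rename(columns={"midpoint": "pos"})
    return GenotypeMatrix(dosages=df, snp_meta=meta)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Genotype dosages from a VCF (``DS`` FORMAT field, ``GT`` fallback)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, pos, ref, alt = [], [], [], [], []
    columns = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(
                float
            )
        ids.append(vid)
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        columns.append(ds)
    if not ids:
        raise ValueError(f"{path}: no variants")
    dosages = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(samples, name="sample"), columns=ids
    )
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "coded_allele": alt, "other_allele": ref},
        index=pd.Index(ids, name="snp"),
    )
    return GenotypeMatrix(dosages=dosages, snp_meta=meta)


def read_expression_tsv(path: str | Path, annot_path: str | Path) -> ExpressionMatrix:
    """Sample-by-probe TSV plus probe annotation (probe, chrom, midpoint, gene)."""
    df = _read_matrix(path).astype(float)
    meta = pd.read_csv(annot_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, probe_meta=meta)


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return _read_matrix(path)


def read_summary_stats(
    path: str | Path,
    trait: str,
    case_control: bool = False,
    case_fraction: float | None = None,
) -> RegionalAssoc:
    """Regional summary-stat TSV: snp_id, pos, then (beta, se) or (p, maf, n)."""
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'snp_id'")
    return RegionalAssoc(
        trait=trait, table=df, case_control=case_control, case_fraction=case_fraction
    )


def write_eqtl_records(
    records: pd.DataFrame,
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    path: str | Path,
) -> None:
    """eQTL record TSV with genomic coordinates attached."""
    out = records.copy()
    out["chrom_snp"] = out["snp_id"].map(g.snp_meta["chrom"])
    out["pos_snp"] = out["snp_id"].map(g.snp_meta["pos"])
    out["chrom_probe"] = out["probe_id"].map(expr.probe_meta["chrom"])
    out["midpoint"] = out["probe_id"].map(expr.probe_meta["midpoint"])
    cols = [
        "snp_id",
        "probe_id",
        "chrom_snp",
        "pos_snp",
        "chrom_probe",
        "midpoint",
        "rho",
        "p_nominal",
        "q_value",
        "n_used",
        "scope",
    ]
    out[cols].to_csv(path, sep="\t", index=False, na_rep=".")
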
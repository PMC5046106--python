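"""Readers for phenotype/covariate TSV, VCF and PLINK .raw genotype files.

All readers return pandas DataFrames indexed by sample id; ``align_samples``
intersects and order-normalizes ids across tables.  Genotypes are additive
minor/ALT-allele counts; missing calls become NaN and are dropped per
variant by the testing front end (complete-case analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_phenotypes_tsv",
    "read_covariates_tsv",
    "read_genotypes_vcf",
    "read_genotypes_raw",
    "read_pvalue_matrix",
    "align_samples",
]


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Read a TSV with a header and a sample_id column; numeric columns only."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype TSV must have a 'sample_id' column")
    df = df.set_index("sample_id")
    return df.astype(np.float64)


read_covariates_tsv = read_phenotypes_tsv


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF into a samples x variants dosage table.

    Additive coding counts ALT alleles (0/1/2); missing or non-diploid calls
    become NaN.  Multiallelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for j, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            continue
        # gt_types: 0=hom ref, 1=het, 3=hom alt, 2=unknown
        gt = variant.gt_types.astype(np.float64)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                         default=np.nan)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        cols.append(dose)
    vcf.close()
    if not cols:
        raise ValueError("no biallelic variants found in VCF")
    return pd.DataFrame(np.column_stack(cols), index=pd.Index(samples,
                        name="sample_id"), columns=ids)


def read_genotypes_raw(path) -> pd.DataFrame:
    """Read a PLINK --recode A (.raw) file into a samples x variants table."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"IID": str})
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f".raw file lacks columns {missing}")
    out = df.drop(columns=meta).astype(np.float64)
    out.index = pd.Index(df["IID"].values, name="sample_id")
    return out


def read_pvalue_matrix(path) -> pd.DataFrame:
    """Read a variants x phenotypes p-value TSV (variant_id first column)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    vals = df.astype(np.float64)
    if ((vals.values <= 0) | (vals.values > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return vals


def align_samples(*tables: pd.DataFrame) -> tuple[pd.DataFrame, ...]:
    """Restrict all tables to their common sample ids, in sorted order."""
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no samples shared across inputs")
    common = common.sort_values()
    return tuple(t.loc[common] for t in tables)
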
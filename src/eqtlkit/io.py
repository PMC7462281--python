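"""Readers and writers for the on-disk formats the pipeline exchanges.

Genotypes: VCF (DS format field preferred, GT converted to dosage
otherwise) or a plain dosage TSV (variant metadata columns then one
dosage column per sample, missing = "."). Expression: GTEx-style
phenotype BED (chrom, start, end, gene_id, one column per sample;
0-based starts converted on read) plus a gene-annotation sidecar TSV
with strand and biotype. Covariates and GWAS tables are plain TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Covariates, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf_dosages",
    "read_expression_bed",
    "write_expression_bed",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_covariates_tsv",
    "write_covariates_tsv",
    "read_gwas_tsv",
    "write_gwas_tsv",
    "summaries_to_frame",
]

_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in df.columns if c in _META_COLS or c in ("maf", "info_score")]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = (
        df[sample_cols].replace(".", np.nan).apply(pd.to_numeric).to_numpy().T
    )
    variants = df[meta_cols].copy()
    return GenotypeMatrix(dosages=dosages, samples=sample_cols, variants=variants)


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = geno.variants[
        [c for c in _META_COLS + ["maf", "info_score"] if c in geno.variants.columns]
    ].copy()
    dos = pd.DataFrame(geno.dosages.T, columns=geno.samples)
    dos = dos.where(~dos.isna(), ".")
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """VCF reader: per-sample DS field when present, else GT hard calls."""
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # diallelic only
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            dose = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1)).astype(float)
        rows.append(dose)
        meta.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    return GenotypeMatrix(
        dosages=np.array(rows).T if rows else np.empty((len(samples), 0)),
        samples=samples,
        variants=pd.DataFrame(meta, columns=_META_COLS),
    )


def read_expression_bed(
    path: str | Path, annotation: str | Path | None = None, state: str = "counts"
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.rename(columns={df.columns[0]: "chrom"})
    df["chrom"] = df["chrom"].str.lstrip("#")
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "gene_id")]
    genes = df[["gene_id", "chrom", "start", "end"]].copy()
    genes["start"] = genes["start"].astype(int) + 1  # BED 0-based -> 1-based
    genes["end"] = genes["end"].astype(int)
    genes["strand"] = "+"
    genes["biotype"] = "other"
    if annotation is not None:
        ann = read_gene_annotation(annotation).set_index("gene_id")
        genes["strand"] = genes["gene_id"].map(ann["strand"]).fillna("+")
        genes["biotype"] = genes["gene_id"].map(ann["biotype"]).fillna("other")
    return ExpressionMatrix(
        values=df[sample_cols].to_numpy(dtype=float),
        genes=genes,
        samples=sample_cols,
        state=state,
    )


def write_expression_bed(expr: ExpressionMatrix, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "#chrom": expr.genes["chrom"],
            "start": expr.genes["start"].astype(int) - 1,
            "end": expr.genes["end"].astype(int),
            "gene_id": expr.genes["gene_id"],
        }
    )
    vals = pd.DataFrame(expr.values, columns=expr.samples)
    pd.concat([out, vals], axis=1).rename(columns={"#chrom": "chrom"}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["gene_id", "chrom", "start", "end", "strand", "biotype"] if c in genes]
    genes[cols].to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path: str | Path) -> Covariates:
    """Numeric covariate columns; a ``dataset`` label column is ignored."""
    df = pd.read_csv(path, sep="\t")
    samples = df["sample_id"].astype(str).tolist()
    names = [c for c in df.columns if c not in ("sample_id", "dataset")]
    return Covariates(values=df[names].to_numpy(dtype=float), names=names, samples=samples)


def write_covariates_tsv(cov: Covariates, path: str | Path) -> None:
    df = pd.DataFrame(cov.values, columns=cov.names)
    df.insert(0, "sample_id", cov.samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "p_value" in df.columns and "gwas_p" not in df.columns:
        df = df.rename(columns={"p_value": "gwas_p"})
    return df


def write_gwas_tsv(gwas: pd.DataFrame, path: str | Path) -> None:
    out = gwas.rename(columns={"gwas_p": "p_value"})
    out.to_csv(path, sep="\t", index=False)


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Per-gene summary table (one row per tested gene)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "gene_id": s.gene_id,
                "n_cis_variants": s.n_cis_variants,
                "best_variant": s.best.variant_id if s.best else "",
                "slope": s.best.slope if s.best else np.nan,
                "nominal_p": s.best.nominal_p if s.best else np.nan,
                "beta_shape1": s.beta_shape1,
                "beta_shape2": s.beta_shape2,
                "perm_p_direct": s.perm_p_direct,
                "perm_p_beta": s.perm_p_beta,
                "n_permutations": s.n_permutations,
                "q_value": s.q_value,
                "nominal_threshold": s.nominal_threshold,
                "is_egene": s.is_egene,
            }
        )
    return pd.DataFrame(rows)
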
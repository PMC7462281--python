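"""End-to-end orchestration: QC -> normalize -> cis scan -> conditional ->
clusters -> GWAS integration, plus a simulate-and-validate harness that
scores every stage against the planted truth of a synthetic dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as clu
from . import gwas as gw
from . import io as eio
from . import normalize as norm
from .coloc import ColocPriors
from .conditional import compile_signals, conditional_scan_all
from .containers import Covariates, ExpressionMatrix, GenotypeMatrix
from .mapping import CisWindow, map_cis, nominal_scan, summarize_catalogue
from .qc import QcParams, filter_variants, genotype_pca, kinship_filter
from .simulate import SimulationConfig, simulate_expression, simulate_genotypes, simulate_gwas

log = logging.getLogger("eqtlkit")

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "run_pipeline", "simulate_and_validate"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run (paper defaults baked in)."""

    genotypes: str = ""
    expression: str = ""
    annotation: str = ""
    covariates: str = ""
    gwas: str = ""
    out_dir: str = "eqtlkit_out"
    qc: QcParams = field(default_factory=QcParams)
    cis_window: int = 1_000_000
    perm_min: int = 1000
    perm_max: int = 10000
    qvalue_lambda: float = 0.85
    fdr: float = 0.05
    n_genotype_pcs: int = 5
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    cluster_min_genes: int = 3
    cluster_max_gap: int = 1_000_000
    h4_threshold: float = 0.8
    gwas_r2_max: float = 0.5
    seed: int = 0


@dataclass
class PipelineResult:
    geno: GenotypeMatrix
    expr: ExpressionMatrix
    covariates: Covariates
    summaries: list
    catalogue: pd.DataFrame
    signal_table: pd.DataFrame
    signal_counts: dict
    cluster_list: list
    cluster_table: pd.DataFrame
    cluster_counts: dict
    overlaps: pd.DataFrame | None = None
    overlap_counts: dict | None = None
    enrichment: dict | None = None
    multi_trait: pd.DataFrame | None = None
    qc_log: dict | None = None
    catalogue_summary: dict | None = None


def _build_covariates(
    base: Covariates, expr: ExpressionMatrix, geno: GenotypeMatrix, n_pcs: int
) -> Covariates:
    """Base covariates + study-site dummies + genotype PCs."""
    cov = base
    if expr.dataset is not None:
        sites = pd.Series(expr.dataset)
        uniq = sites.unique()
        for s in uniq[1:]:  # first level is the reference
            cov = cov.with_columns((sites == s).to_numpy(float), [f"site_{s}"])
    if n_pcs > 0:
        pcs = genotype_pca(geno, n_components=n_pcs)
        cov = cov.with_columns(pcs.to_numpy(), list(pcs.columns))
    return cov


def _normalize_counts(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, dict]:
    """Per-dataset TMM/CPM + expression filter, merge, quantile, batch adjust."""
    datasets = sorted(set(expr.dataset)) if expr.dataset else ["all"]
    per_ds: dict[str, ExpressionMatrix] = {}
    for d in datasets:
        idx = (
            np.flatnonzero(np.array(expr.dataset) == d)
            if expr.dataset
            else np.arange(expr.n_samples)
        )
        sub = ExpressionMatrix(
            values=expr.values[:, idx],
            genes=expr.genes.copy(),
            samples=[expr.samples[i] for i in idx],
            state="counts",
            dataset=[d] * idx.size,
        )
        per_ds[d] = norm.cpm(sub)
    shared, summary = norm.expression_filter(per_ds)
    shared_set = set(shared)
    keep = expr.genes["gene_id"].isin(shared_set).to_numpy()
    merged_vals = np.column_stack([per_ds[d].values for d in datasets])
    merged_samples = [s for d in datasets for s in per_ds[d].samples]
    merged_ds = [d for d in datasets for _ in per_ds[d].samples]
    # restore original sample order
    order = [merged_samples.index(s) for s in expr.samples]
    merged = ExpressionMatrix(
        values=merged_vals[keep][:, order],
        genes=expr.genes[keep].reset_index(drop=True),
        samples=list(expr.samples),
        state="cpm",
        dataset=[merged_ds[i] for i in order],
    )
    quant = norm.log_quantile_normalize(merged)
    adjusted = norm.batch_adjust(quant) if len(datasets) > 1 else quant.with_values(
        quant.values.copy(), "batch_adjusted"
    )
    info = {
        "n_genes_input": expr.n_genes,
        "n_genes_shared": len(shared),
        "n_failing_intersection": summary.attrs["n_failing_intersection"],
        "outlier_flags": norm.sample_pca_outliers(adjusted),
    }
    return adjusted, info


def run_pipeline(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Covariates,
    gwas: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """All stages on in-memory inputs. See :func:`run_all` for file I/O."""
    cfg = config or PipelineConfig()

    geno_qc, flog = filter_variants(geno, cfg.qc)
    geno_qc, removed = kinship_filter(geno_qc, cfg.qc.kinship_max, seed=cfg.seed)
    if removed:
        keep = [s for s in expr.samples if s in set(geno_qc.samples)]
        sidx = [expr.samples.index(s) for s in keep]
        expr = ExpressionMatrix(
            values=expr.values[:, sidx],
            genes=expr.genes.copy(),
            samples=keep,
            state=expr.state,
            dataset=[expr.dataset[i] for i in sidx] if expr.dataset else None,
        )
        covariates = Covariates(
            values=covariates.values[[covariates.samples.index(s) for s in keep]],
            names=covariates.names,
            samples=keep,
        )
    log.info("QC: %d variants kept, %d samples removed", geno_qc.n_variants, len(removed))

    expr_norm, norm_info = _normalize_counts(expr)
    cov_full = _build_covariates(covariates, expr_norm, geno_qc, cfg.n_genotype_pcs)

    summaries, catalogue = map_cis(
        geno_qc, expr_norm, cov_full,
        window=cfg.cis_window, perm_min=cfg.perm_min, perm_max=cfg.perm_max,
        fdr=cfg.fdr, lambda_=cfg.qvalue_lambda, seed=cfg.seed,
    )
    cat_summary = summarize_catalogue(summaries, catalogue, expr_norm.genes)

    signals = conditional_scan_all(
        geno_qc, expr_norm, cov_full, summaries, window=cfg.cis_window
    )
    signal_table, signal_counts = compile_signals(signals)

    multi = clu.multi_gene_evariants(catalogue, cfg.cluster_min_genes)
    cluster_list = clu.merge_into_clusters(
        multi, geno_qc.variants, max_gap=cfg.cluster_max_gap
    )
    if cluster_list:
        gene_stats = _cluster_gene_stats(geno_qc, expr_norm, cov_full, cluster_list, cfg)
        for c in cluster_list:
            clu.colocalize_cluster(c, gene_stats, cfg.coloc_priors)
            clu.group_coregulated(c, cfg.h4_threshold)
    cluster_table, cluster_counts = clu.cluster_report(cluster_list)

    overlaps = overlap_counts = enrichment = multi_trait = None
    if gwas is not None and len(gwas):
        sig = gw.filter_genome_wide(gwas)
        pruned, absent = gw.ld_prune_gwas(sig, geno_qc, cfg.gwas_r2_max)
        overlaps, overlap_counts = gw.overlap_evariants(pruned, catalogue, geno_qc.variants)
        n_all = geno_qc.n_variants
        k_all = cat_summary["n_unique_evariants"]
        enrichment = gw.enrichment_test(
            overlap_counts["n_overlap_variants"],
            overlap_counts["n_gwas_variants"],
            k_all,
            n_all,
        )
        enrichment["n_absent_from_genotypes"] = len(absent)
        multi_trait = gw.multi_trait_egenes(overlaps)

    return PipelineResult(
        geno=geno_qc,
        expr=expr_norm,
        covariates=cov_full,
        summaries=summaries,
        catalogue=catalogue,
        signal_table=signal_table,
        signal_counts=signal_counts,
        cluster_list=cluster_list,
        cluster_table=cluster_table,
        cluster_counts=cluster_counts,
        overlaps=overlaps,
        overlap_counts=overlap_counts,
        enrichment=enrichment,
        multi_trait=multi_trait,
        qc_log={"variant_filters": flog.as_dict(), "samples_removed": removed,
                **norm_info},
        catalogue_summary=cat_summary,
    )


def _cluster_gene_stats(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    cov: Covariates,
    cluster_list: list,
    cfg: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Full cis traces for every gene appearing in any cluster."""
    needed = sorted({g for c in cluster_list for g in c.gene_ids})
    gene_row = {g: i for i, g in enumerate(expr.genes["gene_id"])}
    tss = expr.tss()
    out: dict[str, pd.DataFrame] = {}
    for g in needed:
        if g not in gene_row:
            continue
        i = gene_row[g]
        grow = expr.genes.iloc[i]
        win = CisWindow.for_gene(g, grow["chrom"], grow["start"], grow["end"], cfg.cis_window)
        idx = np.flatnonzero(win.variant_mask(geno.variants))
        if idx.size == 0:
            continue
        recs = nominal_scan(
            g, geno.dosages[:, idx], geno.variants.iloc[idx].reset_index(drop=True),
            expr.values[i], cov, tss=int(tss[i]), strand=str(grow["strand"]),
        )
        out[g] = pd.DataFrame([r.as_dict() for r in recs])
    return out


def run_all(config: PipelineConfig) -> dict:
    """File-driven run: read inputs, execute all stages, write outputs.

    Writes per-stage TSVs plus ``manifest.json`` with parameters, seeds
    and per-stage record counts. Returns the manifest dict.
    """
    for fld in ("genotypes", "expression", "covariates"):
        path = getattr(config, fld)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config field {fld!r}: missing input path {path!r}")
    geno = (
        eio.read_vcf_dosages(config.genotypes)
        if str(config.genotypes).endswith((".vcf", ".vcf.gz"))
        else eio.read_dosage_tsv(config.genotypes)
    )
    expr = eio.read_expression_bed(
        config.expression, annotation=config.annotation or None
    )
    cov_df = pd.read_csv(config.covariates, sep="\t")
    dataset = None
    if "dataset" in cov_df.columns:
        dataset = cov_df["dataset"].astype(str).tolist()
        cov_df = cov_df.drop(columns=["dataset"])
    samples = cov_df["sample_id"].astype(str).tolist()
    names = [c for c in cov_df.columns if c != "sample_id"]
    covariates = Covariates(cov_df[names].to_numpy(float), names, samples)
    expr.dataset = dataset
    gwas = eio.read_gwas_tsv(config.gwas) if config.gwas else None

    res = run_pipeline(geno, expr, covariates, gwas, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.summaries_to_frame(res.summaries).to_csv(out / "genes.tsv", sep="\t", index=False)
    res.catalogue.to_csv(out / "significant_pairs.tsv", sep="\t", index=False)
    res.signal_table.to_csv(out / "independent_signals.tsv", sep="\t", index=False)
    res.cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    if res.cluster_list:
        pd.DataFrame(
            [r.as_dict() for c in res.cluster_list for r in c.pair_results]
        ).to_csv(out / "cluster_pairs_h4.tsv", sep="\t", index=False)
    if res.overlaps is not None:
        res.overlaps.to_csv(out / "gwas_overlap.tsv", sep="\t", index=False)
        res.multi_trait.to_csv(out / "gwas_multi_trait_egenes.tsv", sep="\t", index=False)

    manifest = {
        "params": {
            "cis_window": config.cis_window,
            "perm_min": config.perm_min,
            "perm_max": config.perm_max,
            "qvalue_lambda": config.qvalue_lambda,
            "fdr": config.fdr,
            "n_genotype_pcs": config.n_genotype_pcs,
            "cluster_min_genes": config.cluster_min_genes,
            "cluster_max_gap": config.cluster_max_gap,
            "h4_threshold": config.h4_threshold,
            "gwas_r2_max": config.gwas_r2_max,
            "seed": config.seed,
            "qc": asdict(config.qc),
            "coloc_priors": asdict(config.coloc_priors),
        },
        "qc": res.qc_log,
        "catalogue": res.catalogue_summary,
        "signals": res.signal_counts,
        "clusters": res.cluster_counts,
        "gwas": {"overlap": res.overlap_counts, "enrichment": res.enrichment},
        "records": {
            "genes.tsv": len(res.summaries),
            "significant_pairs.tsv": int(len(res.catalogue)),
            "independent_signals.tsv": int(len(res.signal_table)),
            "clusters.tsv": int(len(res.cluster_table)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _block_of(variant_id: str, block_size: int) -> int:
    return int(variant_id.removeprefix("var")) // block_size


def simulate_and_validate(
    sim_config: SimulationConfig,
    pipeline_config: PipelineConfig | None = None,
    n_traits: int = 6,
    gwas_overlap_fraction: float = 0.3,
) -> dict:
    """Generate a synthetic study, run the pipeline, score against truth.

    Returns eGene sensitivity and false-call fraction, secondary-signal
    recovery, co-regulated-group Jaccard vs the planted groups, and
    GWAS-overlap recovery.
    """
    cfg = pipeline_config or PipelineConfig(seed=sim_config.seed)
    geno = simulate_genotypes(sim_config)
    expr, cov, truth = simulate_expression(geno, sim_config)
    gwas = (
        simulate_gwas(truth, n_traits, gwas_overlap_fraction, seed=sim_config.seed)
        if n_traits > 0
        else None
    )
    res = run_pipeline(geno, expr, cov, gwas, cfg)

    called = {s.gene_id for s in res.summaries if s.is_egene}
    planted = truth.egene_ids()
    sens = len(called & planted) / len(planted) if planted else float("nan")
    false_frac = len(called - planted) / len(called) if called else 0.0

    # secondary-signal recovery: genes with a planted independent second causal
    two_causal = truth.genes[
        (truth.genes["secondary_variant"] != "") & truth.genes["is_egene"]
    ]
    n_recovered2 = 0
    sig_by_gene = (
        res.signal_table.groupby("gene_id")
        if len(res.signal_table)
        else None
    )
    for _, row in two_causal.iterrows():
        if sig_by_gene is None or row["gene_id"] not in sig_by_gene.groups:
            continue
        sub = sig_by_gene.get_group(row["gene_id"])
        if len(sub) < 2:
            continue
        blocks = {
            _block_of(v, sim_config.block_size) for v in sub["variant_id"]
        }
        want = {
            _block_of(row["causal_variant"], sim_config.block_size),
            _block_of(row["secondary_variant"], sim_config.block_size),
        }
        if want <= blocks:
            n_recovered2 += 1
    sec_recovery = n_recovered2 / len(two_causal) if len(two_causal) else float("nan")

    # co-regulated group recovery: best-match Jaccard per planted group
    planted_groups = [
        set(sub["gene_id"])
        for gid, sub in truth.genes[truth.genes["group_id"] >= 0].groupby("group_id")
    ]
    found_groups = [g for c in res.cluster_list for g in c.groups]
    jaccards = []
    for pg in planted_groups:
        best = 0.0
        for fg in found_groups:
            j = len(pg & fg) / len(pg | fg)
            best = max(best, j)
        jaccards.append(best)
    group_jaccard = float(np.mean(jaccards)) if jaccards else float("nan")

    out = {
        "egene_sensitivity": sens,
        "false_egene_fraction": false_frac,
        "n_egenes_called": len(called),
        "n_egenes_planted": len(planted),
        "secondary_signal_recovery": sec_recovery,
        "n_two_causal_genes": int(len(two_causal)),
        "group_jaccard": group_jaccard,
        "n_planted_groups": len(planted_groups),
        "signal_counts": res.signal_counts,
        "cluster_counts": res.cluster_counts,
    }
    if res.overlap_counts is not None:
        truth_frac = gwas_overlap_fraction
        out["gwas_overlap_recovered_fraction"] = (
            res.overlap_counts["n_overlap_variants"]
            / res.overlap_counts["n_gwas_variants"]
        )
        out["gwas_overlap_truth_fraction"] = truth_frac
        out["gwas_enrichment"] = res.enrichment
    out["_result"] = res
    out["_truth"] = truth
    return out
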
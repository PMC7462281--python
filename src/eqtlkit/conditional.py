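"""Iterative forward discovery of independent cis-eQTL signals.

For each eGene the primary signal is its best eVariant from the
permutation pass. Discovered signal dosages are then added to the
covariate set and the cis window is rescanned; whenever the minimum
nominal p-value still beats the gene-specific nominal threshold, the
minimizing variant becomes the next-rank signal. The loop stops when no
variant passes the threshold (or at a safety rank cap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Covariates, ExpressionMatrix, GeneEqtlSummary, GenotypeMatrix
from .mapping import CisWindow, nominal_scan

__all__ = ["IndependentSignal", "conditional_scan", "compile_signals"]

MAX_RANK = 10


@dataclass
class IndependentSignal:
    gene_id: str
    rank: int  # 1 = primary, 2+ = conditional rounds
    variant_id: str
    nominal_p: float
    slope: float
    tss_distance: int = 0


def conditional_scan(
    summary: GeneEqtlSummary,
    dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    expression: np.ndarray,
    covariates: Covariates,
    tss: int | None = None,
    strand: str = "+",
    max_rank: int = MAX_RANK,
) -> list[IndependentSignal]:
    """Forward stepwise signal discovery for one eGene.

    Requires ``summary.is_egene`` and a finite nominal threshold from the
    primary pass. Variants in perfect LD with already-discovered signals
    (rank-deficient after inclusion) are skipped in favour of the
    next-best variant.
    """
    if not summary.is_egene or not np.isfinite(summary.nominal_threshold):
        raise ValueError(
            f"conditional scan requires an eGene with a nominal threshold; "
            f"{summary.gene_id} is not one"
        )
    if summary.best is None:
        raise ValueError("eGene summary lacks a best association")
    p_g = summary.nominal_threshold
    vid_index = {v: j for j, v in enumerate(variant_meta["variant_id"])}

    signals = [
        IndependentSignal(
            gene_id=summary.gene_id,
            rank=1,
            variant_id=summary.best.variant_id,
            nominal_p=summary.best.nominal_p,
            slope=summary.best.slope,
            tss_distance=summary.best.tss_distance,
        )
    ]
    cov = covariates
    while len(signals) < max_rank:
        new_col = dosages[:, vid_index[signals[-1].variant_id]]
        cov = cov.with_columns(new_col, [f"signal_rank{len(signals)}"])
        design = cov.design()
        if np.linalg.matrix_rank(design) < design.shape[1]:
            # newly added signal collinear with the existing design; stop
            break
        records = nominal_scan(
            summary.gene_id, dosages, variant_meta, expression, cov,
            tss=tss, strand=strand,
        )
        taken = {s.variant_id for s in signals}
        candidates = sorted(
            (r for r in records if r.nominal_p < p_g),
            key=lambda r: (r.nominal_p, r.variant_id),
        )
        nxt = None
        for cand in candidates:
            if cand.variant_id in taken:
                continue
            probe = cov.with_columns(
                dosages[:, vid_index[cand.variant_id]], ["probe"]
            ).design()
            if np.linalg.matrix_rank(probe) < probe.shape[1]:
                continue  # perfect LD with an existing signal
            nxt = cand
            break
        if nxt is None:
            break
        signals.append(
            IndependentSignal(
                gene_id=summary.gene_id,
                rank=len(signals) + 1,
                variant_id=nxt.variant_id,
                nominal_p=nxt.nominal_p,
                slope=nxt.slope,
                tss_distance=nxt.tss_distance,
            )
        )
    else:
        warnings.warn(
            f"{summary.gene_id}: conditional scan hit the rank cap ({max_rank})"
        )
    return signals


def conditional_scan_all(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Covariates,
    summaries: list[GeneEqtlSummary],
    window: int = 1_000_000,
    max_rank: int = MAX_RANK,
) -> list[IndependentSignal]:
    """Run :func:`conditional_scan` over every eGene."""
    tss_all = expr.tss()
    gene_row = {g: i for i, g in enumerate(expr.genes["gene_id"])}
    signals: list[IndependentSignal] = []
    for s in summaries:
        if not s.is_egene or s.best is None or not np.isfinite(s.nominal_threshold):
            continue
        i = gene_row[s.gene_id]
        grow = expr.genes.iloc[i]
        win = CisWindow.for_gene(
            s.gene_id, grow["chrom"], grow["start"], grow["end"], window
        )
        idx = np.flatnonzero(win.variant_mask(geno.variants))
        signals.extend(
            conditional_scan(
                s,
                geno.dosages[:, idx],
                geno.variants.iloc[idx].reset_index(drop=True),
                expr.values[i],
                covariates,
                tss=int(tss_all[i]),
                strand=str(grow["strand"]),
                max_rank=max_rank,
            )
        )
    return signals


def compile_signals(signals: list[IndependentSignal]) -> tuple[pd.DataFrame, dict]:
    """Tidy signal table plus headline counts.

    Reports primary/secondary/total counts, a histogram of signals per
    gene, and the TSS-distance comparison between primary and conditional
    signals (medians plus a rank-sum test).
    """
    table = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "rank": s.rank,
                "variant_id": s.variant_id,
                "nominal_p": s.nominal_p,
                "slope": s.slope,
                "tss_distance": s.tss_distance,
            }
            for s in sorted(signals, key=lambda s: (s.gene_id, s.rank))
        ],
        columns=["gene_id", "rank", "variant_id", "nominal_p", "slope", "tss_distance"],
    )
    n_primary = int((table["rank"] == 1).sum()) if len(table) else 0
    n_secondary = int((table["rank"] > 1).sum()) if len(table) else 0
    counts: dict = {
        "n_primary": n_primary,
        "n_secondary": n_secondary,
        "n_total": n_primary + n_secondary,
        "signals_per_gene_hist": (
            table.groupby("gene_id").size().value_counts().sort_index().to_dict()
            if len(table)
            else {}
        ),
    }
    prim = table.loc[table["rank"] == 1, "tss_distance"].abs()
    seco = table.loc[table["rank"] > 1, "tss_distance"].abs()
    if len(prim) and len(seco):
        stat = stats.mannwhitneyu(prim, seco, alternative="two-sided")
        counts["tss_distance_median_primary"] = float(prim.median())
        counts["tss_distance_median_secondary"] = float(seco.median())
        counts["tss_distance_ranksum_p"] = float(stat.pvalue)
    return table, counts
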
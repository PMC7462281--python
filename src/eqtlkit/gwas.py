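"""Intersection of trait-associated variants with the eVariant catalogue.

Genome-wide significant GWAS lead variants are LD-pruned per trait
(greedy, most significant kept), intersected with the significant
eVariant catalogue, tested for enrichment with Fisher's exact test, and
annotated with the direction of the expression effect of the risk allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

__all__ = [
    "GWAS_P_MAX",
    "ld_prune_gwas",
    "overlap_evariants",
    "enrichment_test",
    "multi_trait_egenes",
]

GWAS_P_MAX = 5e-8


def filter_genome_wide(gwas: pd.DataFrame, p_max: float = GWAS_P_MAX) -> pd.DataFrame:
    """Keep genome-wide significant rows (p < 5e-8)."""
    return gwas[gwas["gwas_p"] < p_max].reset_index(drop=True)


def ld_prune_gwas(
    gwas: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_max: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy per-trait LD pruning of GWAS lead variants.

    Within each trait, variants are visited by ascending p-value (ties
    broken by position then id); a variant is kept iff its dosage r**2
    with every already-kept variant is <= ``r2_max``. Variants absent
    from the genotype matrix pass through unpruned and are returned as
    the second element for logging.
    """
    vindex = {v: j for j, v in enumerate(geno.variants["variant_id"])}
    pos_map = dict(zip(geno.variants["variant_id"], geno.variants["pos"]))
    kept_rows = []
    absent: list[str] = []
    dos = geno.dosages
    for _, sub in gwas.groupby("trait", sort=True):
        sub = sub.copy()
        sub["_pos"] = sub["variant_id"].map(pos_map).fillna(0).astype(int)
        sub = sub.sort_values(
            ["gwas_p", "_pos", "variant_id"], kind="stable"
        ).drop(columns="_pos")
        kept_cols: list[np.ndarray] = []
        kept_ids: set[str] = set()
        for _, row in sub.iterrows():
            v = row["variant_id"]
            if v not in vindex:
                if v not in kept_ids:
                    absent.append(v)
                    kept_ids.add(v)
                    kept_rows.append(row)
                continue
            if v in kept_ids:
                continue  # duplicate listing: r2 = 1 with itself
            col = dos[:, vindex[v]]
            ok = True
            for prev in kept_cols:
                sd = col.std() * prev.std()
                if sd == 0:
                    continue
                r = np.corrcoef(col, prev)[0, 1]
                if r * r > r2_max:
                    ok = False
                    break
            if ok:
                kept_ids.add(v)
                kept_cols.append(col)
                kept_rows.append(row)
    pruned = pd.DataFrame(kept_rows).reset_index(drop=True)
    return pruned, sorted(set(absent))


def overlap_evariants(
    gwas: pd.DataFrame,
    catalogue: pd.DataFrame,
    variant_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Link GWAS variants to the eGenes they significantly regulate.

    The catalogue slope is the effect of the alt-allele dose; when the
    risk allele is the ref allele the slope sign is flipped so that
    ``direction`` always describes the expression change per risk-allele
    dose (``up`` iff risk-aligned slope > 0). ``risk_allele`` may be the
    literal allele base (matched against the variant record) or one of
    the labels ``ref`` / ``alt``.
    """
    alleles = {}
    if variant_meta is not None:
        alleles = {
            r["variant_id"]: (str(r["ref"]), str(r["alt"]))
            for _, r in variant_meta.iterrows()
        }
    cat = catalogue.set_index("variant_id") if len(catalogue) else catalogue
    rows = []
    flagged = []
    for _, g in gwas.iterrows():
        v = g["variant_id"]
        if len(catalogue) == 0 or v not in cat.index:
            continue
        hits = cat.loc[[v]]
        risk = str(g["risk_allele"])
        if risk in ("ref", "alt"):
            flip = risk == "ref"
        elif v in alleles and risk in alleles[v]:
            flip = risk == alleles[v][0]
        else:
            flagged.append(v)
            flip = None
        for _, h in hits.iterrows():
            slope = float(h["slope"])
            aligned = -slope if flip else slope
            rows.append(
                {
                    "variant_id": v,
                    "trait": g["trait"],
                    "gene_id": h["gene_id"],
                    "slope_alt": slope,
                    "slope_risk": np.nan if flip is None else aligned,
                    "direction": (
                        "" if flip is None else ("up" if aligned > 0 else "down")
                    ),
                }
            )
    overlaps = pd.DataFrame(
        rows,
        columns=["variant_id", "trait", "gene_id", "slope_alt", "slope_risk", "direction"],
    )
    n_unique_gwas = int(gwas["variant_id"].nunique())
    n_overlap = int(overlaps["variant_id"].nunique()) if len(overlaps) else 0
    genes = overlaps.groupby("gene_id")["trait"].nunique() if len(overlaps) else pd.Series(dtype=int)
    counts = {
        "n_gwas_variants": n_unique_gwas,
        "n_overlap_variants": n_overlap,
        "overlap_pct": round(100.0 * n_overlap / n_unique_gwas, 2) if n_unique_gwas else float("nan"),
        "n_linked_egenes": int(genes.size),
        "n_egenes_multi_trait": int((genes >= 2).sum()),
        "n_flagged_risk_allele": len(set(flagged)),
    }
    return overlaps, counts


def enrichment_test(
    k_gwas_evar: int, n_gwas: int, k_all_evar: int, n_all: int
) -> dict:
    """Two-sided Fisher's exact test for eVariant enrichment among GWAS hits.

    2x2 table: [[GWAS eVariants, GWAS non-eVariants],
    [all eVariants, all non-eVariants]]. Returns the odds ratio (None for
    a zero-margin table), the p-value, and both group percentages rounded
    to two decimals.
    """
    if not (0 <= k_gwas_evar <= n_gwas and 0 <= k_all_evar <= n_all):
        raise ValueError("k must satisfy 0 <= k <= n for both groups")
    table = np.array(
        [
            [k_gwas_evar, n_gwas - k_gwas_evar],
            [k_all_evar, n_all - k_all_evar],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {
            "odds_ratio": None,
            "p_value": 1.0,
            "pct_gwas": round(100.0 * k_gwas_evar / n_gwas, 2) if n_gwas else float("nan"),
            "pct_all": round(100.0 * k_all_evar / n_all, 2) if n_all else float("nan"),
        }
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "odds_ratio": float(odds),
        "p_value": float(p),
        "pct_gwas": round(100.0 * k_gwas_evar / n_gwas, 2),
        "pct_all": round(100.0 * k_all_evar / n_all, 2),
    }


def multi_trait_egenes(overlaps: pd.DataFrame) -> pd.DataFrame:
    """(gene, trait, direction) rows for genes linked to >= 2 traits."""
    if len(overlaps) == 0:
        return pd.DataFrame(columns=["gene_id", "trait", "direction"])
    per_gene = overlaps.groupby("gene_id")["trait"].nunique()
    keep = set(per_gene[per_gene >= 2].index)
    out = (
        overlaps[overlaps["gene_id"].isin(keep)][["gene_id", "trait", "direction"]]
        .drop_duplicates()
        .sort_values(["gene_id", "trait"], kind="stable")
        .reset_index(drop=True)
    )
    return out
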
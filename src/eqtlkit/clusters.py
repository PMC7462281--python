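"""Regulatory-cluster detection and per-cluster colocalization.

Multi-gene eVariants (each regulating at least ``min_genes`` eGenes) are
merged along the genome into clusters by single-linkage with a 1 Mbp gap;
every gene pair within a cluster is then tested for a shared causal
signal with the approximate-Bayes-factor colocalization model, and genes
connected by PP(H4) >= 0.8 edges are grouped as co-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .coloc import ColocPriors, ColocResult, coloc_abf

__all__ = [
    "RegulatoryCluster",
    "multi_gene_evariants",
    "merge_into_clusters",
    "colocalize_cluster",
    "group_coregulated",
    "cluster_report",
]

MAX_GAP_BP = 1_000_000
H4_THRESHOLD = 0.8


@dataclass
class RegulatoryCluster:
    """Genomic interval of multi-gene eVariants plus coloc results."""

    chrom: str
    start: int
    end: int
    variant_ids: list[str]
    gene_ids: list[str]
    h4: pd.DataFrame | None = None  # symmetric gene x gene PP(H4)
    pair_results: list[ColocResult] = field(default_factory=list)
    groups: list[set[str]] = field(default_factory=list)
    heatmap_order: list[str] = field(default_factory=list)

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width_bp(self) -> int:
        return self.end - self.start + 1

    def has_group_of(self, k: int = 3) -> bool:
        return any(len(g) >= k for g in self.groups)


def multi_gene_evariants(
    catalogue: pd.DataFrame, min_genes: int = 3
) -> pd.DataFrame:
    """eVariants regulating at least ``min_genes`` distinct eGenes.

    Returns one row per qualifying variant with its eGene list.
    """
    if len(catalogue) == 0:
        return pd.DataFrame(columns=["variant_id", "n_egenes", "gene_ids"])
    per_variant = (
        catalogue.groupby("variant_id")["gene_id"]
        .agg(lambda g: sorted(set(g)))
        .reset_index()
        .rename(columns={"gene_id": "gene_ids"})
    )
    per_variant["n_egenes"] = per_variant["gene_ids"].map(len)
    out = per_variant[per_variant["n_egenes"] >= min_genes].reset_index(drop=True)
    return out[["variant_id", "n_egenes", "gene_ids"]]


def merge_into_clusters(
    variants: pd.DataFrame,
    variant_positions: pd.DataFrame,
    max_gap: int = MAX_GAP_BP,
) -> list[RegulatoryCluster]:
    """Single-linkage 1-D merge of qualifying eVariants.

    Consecutive variants on one chromosome whose gap is strictly below
    ``max_gap`` join one cluster; the cluster interval spans the member
    positions (a singleton cluster has width 1 bp).
    ``variant_positions`` needs columns ``variant_id, chrom, pos``.
    """
    if len(variants) == 0:
        return []
    pos = variant_positions.drop_duplicates("variant_id").set_index("variant_id")
    rows = []
    for _, r in variants.iterrows():
        v = r["variant_id"]
        if v not in pos.index:
            continue
        rows.append(
            {
                "variant_id": v,
                "chrom": str(pos.at[v, "chrom"]),
                "pos": int(pos.at[v, "pos"]),
                "gene_ids": r["gene_ids"],
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable")
    clusters: list[RegulatoryCluster] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        current: list[dict] = []
        last_pos = None
        for _, r in sub.iterrows():
            if last_pos is not None and r["pos"] - last_pos >= max_gap:
                clusters.append(_build_cluster(chrom, current))
                current = []
            current.append(r)
            last_pos = r["pos"]
        if current:
            clusters.append(_build_cluster(chrom, current))
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def _build_cluster(chrom: str, members: list[dict]) -> RegulatoryCluster:
    genes: set[str] = set()
    for m in members:
        genes |= set(m["gene_ids"])
    positions = [m["pos"] for m in members]
    return RegulatoryCluster(
        chrom=str(chrom),
        start=min(positions),
        end=max(positions),
        variant_ids=[m["variant_id"] for m in members],
        gene_ids=sorted(genes),
    )


def colocalize_cluster(
    cluster: RegulatoryCluster,
    gene_stats: dict[str, pd.DataFrame],
    priors: ColocPriors | None = None,
) -> RegulatoryCluster:
    """Pairwise colocalization over a cluster's member genes.

    ``gene_stats`` maps gene_id to its full cis association trace
    (columns ``variant_id, slope, nominal_p`` and optionally
    ``slope_se``). Pairs without overlapping variants get PP(H4) = 0.
    Fills the symmetric H4 matrix and the per-pair results.
    """
    priors = priors or ColocPriors()
    genes = [g for g in cluster.gene_ids if g in gene_stats]
    h4 = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    results: list[ColocResult] = []
    for ga, gb in combinations(genes, 2):
        res = coloc_abf(gene_stats[ga], gene_stats[gb], priors, gene_a=ga, gene_b=gb)
        results.append(res)
        h4.loc[ga, gb] = h4.loc[gb, ga] = res.pp_h4
    cluster.h4 = h4
    cluster.pair_results = results
    return cluster


def group_coregulated(
    cluster: RegulatoryCluster,
    h4_threshold: float = H4_THRESHOLD,
    semantics: str = "components",
) -> RegulatoryCluster:
    """Co-regulated gene groups from the pairwise H4 matrix.

    ``semantics='components'`` (default): connected components of the
    graph with edges at H4 >= threshold, keeping components of size >= 2.
    ``semantics='cliques'``: greedy maximal groups requiring H4 >=
    threshold for *all* pairs inside a group. The heatmap row order comes
    from complete-linkage agglomeration on distance 1 - H4.
    """
    if cluster.h4 is None:
        raise ValueError("run colocalize_cluster first")
    genes = list(cluster.h4.index)
    n = len(genes)
    if n < 2:
        cluster.groups = []
        cluster.heatmap_order = genes
        return cluster
    h4 = cluster.h4.to_numpy(copy=True)
    np.fill_diagonal(h4, 1.0)
    adj = h4 >= h4_threshold

    if semantics == "components":
        seen: set[int] = set()
        groups: list[set[str]] = []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], {i}
            seen.add(i)
            while stack:
                u = stack.pop()
                for v in range(n):
                    if v not in seen and adj[u, v] and v != u:
                        seen.add(v)
                        comp.add(v)
                        stack.append(v)
            if len(comp) >= 2:
                groups.append({genes[i] for i in comp})
    elif semantics == "cliques":
        unassigned = set(range(n))
        groups = []
        while unassigned:
            i = min(unassigned)
            clique = {i}
            for j in sorted(unassigned - {i}):
                if all(adj[j, k] for k in clique):
                    clique.add(j)
            unassigned -= clique
            if len(clique) >= 2:
                groups.append({genes[k] for k in clique})
    else:
        raise ValueError("semantics must be 'components' or 'cliques'")

    cluster.groups = sorted(groups, key=lambda g: (-len(g), sorted(g)))
    dist = 1.0 - h4
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dist = np.nan_to_num(dist, nan=1.0)
    order = leaves_list(linkage(squareform(dist, checks=False), method="complete"))
    cluster.heatmap_order = [genes[i] for i in order]
    return cluster


def cluster_report(clusters: list[RegulatoryCluster]) -> tuple[pd.DataFrame, dict]:
    """Per-cluster TSV-ready table plus headline counts."""
    rows = []
    n_pairs = 0
    n_pairs_above = 0
    n_with_triple = 0
    for c in clusters:
        pairs = len(c.pair_results)
        above = sum(r.pp_h4 >= H4_THRESHOLD for r in c.pair_results)
        n_pairs += pairs
        n_pairs_above += above
        if c.has_group_of(3):
            n_with_triple += 1
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "width_bp": c.width_bp,
                "n_variants": len(c.variant_ids),
                "n_genes": len(c.gene_ids),
                "n_pairs": pairs,
                "n_pairs_h4_ge_0.8": above,
                "groups": ";".join(",".join(sorted(g)) for g in c.groups),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "width_bp", "n_variants",
            "n_genes", "n_pairs", "n_pairs_h4_ge_0.8", "groups",
        ],
    )
    counts = {
        "n_clusters": len(clusters),
        "n_gene_pairs_tested": n_pairs,
        "n_pairs_h4_ge_threshold": n_pairs_above,
        "n_clusters_with_3gene_group": n_with_triple,
    }
    return table, counts
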
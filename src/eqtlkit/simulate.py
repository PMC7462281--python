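"""Synthetic genotype/expression/GWAS generator with planted truth.

The generator emulates a multi-site cis-eQTL study: a few hundred samples
recruited in batches, dosage genotypes with block-wise linkage
disequilibrium, a mixed-biotype gene panel, planted primary and secondary
cis effects, groups of genes sharing one causal variant, batch-shifted
expression counts, and trait-association tables that overlap the planted
eQTL. Every planted fact is returned in a :class:`TruthTable` so each
downstream stage can be scored against known truth.

LD model: per block of consecutive variants, a pool of founder haplotypes
is drawn once; each sample receives the sum of two haplotypes sampled from
the pool. Variants within a block are therefore correlated through shared
founders while blocks are independent. Counts come from a rounded
exponentiated Gaussian, which keeps the library-size/TMM/CPM machinery
downstream meaningful without full negative-binomial simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Covariates, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_gwas",
]

_BIOTYPES = ["protein_coding", "lncRNA", "pseudogene", "TEC", "other"]
_BIOTYPE_WEIGHTS = [0.80, 0.12, 0.04, 0.02, 0.02]  # roughly bulk-tissue mix


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe the desk-scale study the package is validated on:
    three recruitment sites totalling ~300 European-ancestry samples,
    block-LD genotypes, and planted cis effects explaining 20% of
    log-expression variance for half of the genes.
    """

    n_samples: int = 300
    n_batches: int = 3
    batch_sizes: tuple[int, ...] | None = None  # default: near-even split
    n_variants: int = 4000
    n_genes: int = 200
    block_size: int = 20
    n_founder_haplotypes: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    egene_fraction: float = 0.5
    effect_r2: float = 0.2
    secondary_fraction: float = 0.0
    secondary_effect_r2: float | None = None  # defaults to effect_r2
    cluster_specs: tuple[int, ...] = ()  # sizes of shared-causal gene groups
    batch_shift_sd: float = 0.3
    noise_sd: float = 0.5
    gene_spacing: int = 2_000_000  # bp between isolated gene loci
    cluster_gene_spacing: int = 150_000  # bp between genes inside one group
    mean_log_count_range: tuple[float, float] = (3.0, 7.5)  # natural log
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0 or self.n_genes <= 0:
            raise ConfigurationError("dimensions must be positive")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        if self.n_founder_haplotypes < 2:
            raise ConfigurationError("need at least 2 founder haplotypes")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for frac in (self.egene_fraction, self.effect_r2, self.secondary_fraction):
            if not 0 <= frac <= 1:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.batch_sizes is None:
            base = self.n_samples // self.n_batches
            sizes = [base] * self.n_batches
            for i in range(self.n_samples - base * self.n_batches):
                sizes[i] += 1
            self.batch_sizes = tuple(sizes)
        if sum(self.batch_sizes) != self.n_samples:
            raise ConfigurationError("batch_sizes must sum to n_samples")
        if sum(self.cluster_specs) > self.n_genes:
            raise ConfigurationError("cluster_specs request more genes than exist")

    @property
    def n_blocks(self) -> int:
        return int(np.ceil(self.n_variants / self.block_size))


@dataclass
class TruthTable:
    """Everything that was planted, keyed the way downstream calls are."""

    genes: pd.DataFrame  # gene_id, is_egene, causal_variant, secondary_variant,
    #                      beta_primary, beta_secondary, group_id
    variants: pd.DataFrame  # variant_id, planted_maf, is_causal
    gwas_links: pd.DataFrame | None = None  # variant_id, trait, is_planted_causal

    def egene_ids(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_egene"], "gene_id"])

    def causal_variants(self) -> set[str]:
        out = set(self.genes["causal_variant"].dropna())
        out |= set(self.genes["secondary_variant"].dropna())
        out.discard("")
        return out


def _haplotype_pool(rng: np.random.Generator, n_hap: int, freqs: np.ndarray) -> np.ndarray:
    """Founder haplotypes (n_hap x n_variants) hitting the target frequencies."""
    pool = (rng.random((n_hap, freqs.size)) < freqs[None, :]).astype(float)
    # keep every variant polymorphic within the pool
    const = np.flatnonzero(pool.min(axis=0) == pool.max(axis=0))
    for j in const:
        i = rng.integers(n_hap)
        pool[i, j] = 1.0 - pool[i, j]
    return pool


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw block-LD dosages by summing two founder haplotypes per block.

    Positions are laid out so that gene loci built by
    :func:`simulate_expression` each see a local set of cis variants;
    consecutive variants are evenly spaced along one synthetic chromosome.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    # alt allele is the minor allele for planted frequencies
    dosages = np.empty((n, m), dtype=float)
    for b in range(config.n_blocks):
        j0 = b * config.block_size
        j1 = min(j0 + config.block_size, m)
        pool = _haplotype_pool(rng, config.n_founder_haplotypes, freqs[j0:j1])
        picks = rng.integers(config.n_founder_haplotypes, size=(n, 2))
        dosages[:, j0:j1] = pool[picks[:, 0]] + pool[picks[:, 1]]

    span = config.n_genes * config.gene_spacing + config.gene_spacing
    positions = np.linspace(1, span, m).astype(int)
    positions = np.maximum.accumulate(positions + np.arange(m) % 2)  # strictly inc
    ref = rng.choice(list("ACGT"), size=m)
    alt_choices = np.array(list("ACGT"))
    alt = np.array(
        [rng.choice(alt_choices[alt_choices != r]) for r in ref], dtype=object
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j:06d}" for j in range(m)],
            "chrom": "1",
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "info_score": np.clip(rng.normal(0.96, 0.04, size=m), 0.31, 1.0),
            "planted_maf": freqs,
        }
    )
    geno = GenotypeMatrix(
        dosages=dosages,
        samples=[f"S{i:04d}" for i in range(n)],
        variants=variants,
    )
    geno.variants["maf"] = geno.maf()
    return geno


def _pick_causal(
    rng: np.random.Generator,
    cis_idx: np.ndarray,
    maf: np.ndarray,
    exclude_blocks: set[int],
    block_size: int,
    min_maf: float = 0.10,
) -> int | None:
    """A cis variant with workable MAF, outside the excluded LD blocks."""
    ok = [
        j
        for j in cis_idx
        if maf[j] >= min_maf and (j // block_size) not in exclude_blocks
    ]
    if not ok:
        ok = [j for j in cis_idx if (j // block_size) not in exclude_blocks]
    if not ok:
        return None
    return int(rng.choice(ok))


def simulate_expression(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, Covariates, TruthTable]:
    """Plant cis effects and emit counts, covariates and the truth table.

    Log-scale model per gene g and sample s::

        x_gs = mu_g + beta_g d_s + beta2_g d2_s + batch_gb + a_g age_s
               + x_g sex_s + p_g pmi_s + eps,   counts = round(exp(x))

    ``beta_g`` is calibrated so the primary dosage explains ``effect_r2``
    of the genetic-plus-noise variance on the log scale.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, g = config.n_samples, config.n_genes
    maf = geno.maf()
    pos = geno.variants["pos"].to_numpy()
    block_size = config.block_size

    # --- gene layout: cluster groups first (compact loci), then isolated genes
    gene_rows = []
    group_ids = np.full(g, -1, dtype=int)
    cursor = config.gene_spacing
    gi = 0
    cluster_causal: list[int | None] = []
    for group, size in enumerate(config.cluster_specs):
        locus_center = cursor + config.gene_spacing // 2
        for k in range(size):
            start = locus_center + k * config.cluster_gene_spacing
            gene_rows.append((gi, "1", start, start + 20_000))
            group_ids[gi] = group
            gi += 1
        cursor = locus_center + size * config.cluster_gene_spacing + config.gene_spacing
        # shared causal variant: close to all member gene bodies
        center = locus_center + (size * config.cluster_gene_spacing) // 2
        cis = np.flatnonzero(np.abs(pos - center) < 400_000)
        j = _pick_causal(rng, cis, maf, set(), block_size)
        cluster_causal.append(j)
    while gi < g:
        start = cursor
        gene_rows.append((gi, "1", start, start + 20_000))
        cursor += config.gene_spacing
        gi += 1

    strands = rng.choice(["+", "-"], size=g)
    biotypes = rng.choice(_BIOTYPES, size=g, p=_BIOTYPE_WEIGHTS)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(g)],
            "chrom": [r[1] for r in gene_rows],
            "start": [r[2] for r in gene_rows],
            "end": [r[3] for r in gene_rows],
            "strand": strands,
            "biotype": biotypes,
        }
    )

    # --- choose eGenes and causal variants
    n_cluster_genes = int(sum(config.cluster_specs))
    n_egenes = max(int(round(config.egene_fraction * g)), n_cluster_genes)
    free = np.arange(n_cluster_genes, g)
    extra = rng.choice(free, size=n_egenes - n_cluster_genes, replace=False)
    is_egene = np.zeros(g, dtype=bool)
    is_egene[:n_cluster_genes] = True
    is_egene[extra] = True

    sec_r2 = (
        config.effect_r2
        if config.secondary_effect_r2 is None
        else config.secondary_effect_r2
    )
    causal = np.full(g, "", dtype=object)
    secondary = np.full(g, "", dtype=object)
    beta1 = np.zeros(g)
    beta2 = np.zeros(g)
    vid = geno.variants["variant_id"].to_numpy()

    dos = geno.dosages
    sd_d = dos.std(axis=0, ddof=0)

    def effect_size(j: int, r2: float) -> float:
        if r2 <= 0 or sd_d[j] == 0:
            return 0.0
        return float(np.sqrt(r2 / (1 - r2)) * config.noise_sd / sd_d[j])

    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    secondary_pool = np.flatnonzero(is_egene[n_cluster_genes:]) + n_cluster_genes
    n_secondary = int(round(config.secondary_fraction * n_egenes))
    has_secondary = set(
        rng.choice(secondary_pool, size=min(n_secondary, secondary_pool.size), replace=False)
        if secondary_pool.size
        else []
    )

    for i in range(g):
        if not is_egene[i]:
            continue
        if group_ids[i] >= 0:
            j = cluster_causal[group_ids[i]]
        else:
            cis = np.flatnonzero((pos >= starts[i] - 1_000_000) & (pos <= ends[i] + 1_000_000))
            j = _pick_causal(rng, cis, maf, set(), block_size)
        if j is None:
            is_egene[i] = False
            continue
        causal[i] = vid[j]
        beta1[i] = effect_size(j, config.effect_r2)
        if i in has_secondary:
            cis = np.flatnonzero((pos >= starts[i] - 1_000_000) & (pos <= ends[i] + 1_000_000))
            j2 = _pick_causal(rng, cis, maf, {j // block_size}, block_size)
            if j2 is not None:
                secondary[i] = vid[j2]
                beta2[i] = effect_size(j2, sec_r2)

    # --- covariates
    batch = np.repeat(np.arange(config.n_batches), config.batch_sizes)
    age = rng.normal(65, 10, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pmi = np.clip(rng.normal(30, 10, size=n), 2, None)
    covariates = Covariates(
        values=np.column_stack([age, sex, pmi]),
        names=["age", "sex", "pmi"],
        samples=list(geno.samples),
    )

    # --- log-scale signal
    mu = rng.uniform(*config.mean_log_count_range, size=g)
    batch_shift = rng.normal(0, config.batch_shift_sd, size=(g, config.n_batches))
    age_coef = rng.normal(0, 0.002, size=g)
    sex_coef = rng.normal(0, 0.05, size=g)
    pmi_coef = rng.normal(0, 0.003, size=g)

    x = mu[:, None] + rng.normal(0, config.noise_sd, size=(g, n))
    x += batch_shift[:, batch]
    x += age_coef[:, None] * (age - age.mean())[None, :]
    x += sex_coef[:, None] * (sex - sex.mean())[None, :]
    x += pmi_coef[:, None] * (pmi - pmi.mean())[None, :]
    vindex = {v: j for j, v in enumerate(vid)}
    for i in range(g):
        if causal[i]:
            x[i] += beta1[i] * dos[:, vindex[causal[i]]]
        if secondary[i]:
            x[i] += beta2[i] * dos[:, vindex[secondary[i]]]

    counts = np.rint(np.exp(x))
    expr = ExpressionMatrix(
        values=counts,
        genes=genes,
        samples=list(geno.samples),
        state="counts",
        dataset=[f"site{b}" for b in batch],
    )

    truth_genes = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "is_egene": is_egene,
            "causal_variant": causal,
            "secondary_variant": secondary,
            "beta_primary": beta1,
            "beta_secondary": beta2,
            "group_id": group_ids,
        }
    )
    causal_set = set(causal[causal != ""]) | set(secondary[secondary != ""])
    truth_variants = pd.DataFrame(
        {
            "variant_id": vid,
            "planted_maf": geno.variants["planted_maf"].to_numpy(),
            "is_causal": [v in causal_set for v in vid],
        }
    )
    truth = TruthTable(genes=truth_genes, variants=truth_variants)
    return expr, covariates, truth


def simulate_gwas(
    truth: TruthTable,
    n_traits: int = 12,
    overlap_fraction: float = 0.3,
    seed: int = 0,
    variants_per_trait: list[int] | None = None,
) -> pd.DataFrame:
    """Trait-association tables that partially reuse planted causal variants.

    ``overlap_fraction`` of the rows point at planted causal eQTL variants,
    the rest at non-causal variants. Returns a tidy table with columns
    ``variant_id, trait, risk_allele, gwas_p, study``.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ConfigurationError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    causal = truth.variants.loc[truth.variants["is_causal"], "variant_id"].to_numpy()
    noncausal = truth.variants.loc[~truth.variants["is_causal"], "variant_id"].to_numpy()
    if variants_per_trait is None:
        variants_per_trait = list(rng.integers(3, 25, size=n_traits))
    if len(variants_per_trait) != n_traits:
        raise ConfigurationError("variants_per_trait length must equal n_traits")

    rows = []
    for t, count in enumerate(variants_per_trait):
        n_overlap = int(round(overlap_fraction * count))
        if causal.size == 0:
            n_overlap = 0
        # replacement only when more overlap rows are requested than
        # causal variants exist; duplicates are collapsed by LD pruning
        chosen = list(
            rng.choice(causal, size=n_overlap, replace=n_overlap > causal.size)
            if n_overlap
            else []
        )
        chosen += list(
            rng.choice(noncausal, size=count - n_overlap, replace=False)
        )
        for v in chosen:
            rows.append(
                {
                    "variant_id": v,
                    "trait": f"trait{t:02d}",
                    "risk_allele": "alt" if rng.random() < 0.5 else "ref",
                    "gwas_p": 10.0 ** (-rng.uniform(8.1, 30.0)),
                    "study": f"study{t:02d}",
                    "is_planted_causal": v in set(causal),
                }
            )
    gwas = pd.DataFrame(rows)
    truth.gwas_links = gwas[["variant_id", "trait", "is_planted_causal"]].copy()
    return gwas
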
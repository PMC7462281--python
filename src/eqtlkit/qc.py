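"""Variant- and sample-level genotype quality control.

Implements the classical imputed-dosage QC battery: autosome restriction,
monomorphic-variant removal, exact Hardy-Weinberg testing on hard-called
genotypes, call-rate / MAF / imputation-quality thresholds, allele-frequency
concordance with a reference panel, duplicate/related-sample removal via a
standardized-genotype kinship estimate, and genotype PCA for covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "QcParams",
    "hwe_test",
    "filter_variants",
    "compare_allele_freq",
    "kinship_filter",
    "genotype_pca",
]

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


@dataclass
class QcParams:
    """Variant/sample QC thresholds (conventional imputed-GWAS defaults)."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.95
    freq_dev_max: float = 0.13
    kinship_max: float = 0.80
    info_min: float = 0.3


@dataclass
class FilterLog:
    """Per-criterion attrition counts, in application order."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int) -> None:
        self.steps.append((name, int(n_removed)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Uses the standard exact-test recursion over heterozygote counts
    conditional on the allele counts: p = sum of probabilities of all het
    configurations no more probable than the observed one. Returns a value
    in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("HWE test undefined for zero total genotypes")

    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele copies
    # feasible het counts share parity with n_rare
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if het_values.size == 0:
        return 1.0

    # unnormalized log-probabilities via the hypergeometric-style recursion
    logp = np.zeros(het_values.size)
    for k in range(1, het_values.size):
        het = het_values[k]
        hom_r = (n_rare - het) // 2  # rare homozygotes at this het count
        hom_c = n - het - hom_r
        # P(het) / P(het-2) = 4 * hom_r_prev * hom_c_prev / (het * (het - 1))
        prev_hom_r = hom_r + 1
        prev_hom_c = hom_c + 1
        logp[k] = logp[k - 1] + np.log(4.0 * prev_hom_r * prev_hom_c) - np.log(
            het * (het - 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = np.searchsorted(het_values, n_het)
    if obs >= het_values.size or het_values[obs] != n_het:
        raise ValueError(
            f"het count {n_het} infeasible for allele counts (parity mismatch)"
        )
    p_obs = probs[obs]
    # tolerance keeps ties at the observed probability included
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Nearest-integer genotype calls; NaN preserved."""
    return np.where(np.isnan(dosages), np.nan, np.clip(np.rint(dosages), 0, 2))


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per variant, on hard-called dosages."""
    calls = _hard_calls(geno.dosages)
    out = np.empty(geno.n_variants)
    for j in range(geno.n_variants):
        col = calls[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def filter_variants(
    geno: GenotypeMatrix, params: QcParams | None = None
) -> tuple[GenotypeMatrix, FilterLog]:
    """Apply the variant-level QC battery in a fixed, logged order.

    Order: autosomes -> monomorphic -> HWE -> call rate -> info score -> MAF.
    Returns the filtered matrix and an attrition log.
    """
    params = params or QcParams()
    log = FilterLog()
    keep = np.ones(geno.n_variants, dtype=bool)

    chrom = geno.variants["chrom"].astype(str).to_numpy()
    step = ~np.isin(chrom, list(AUTOSOMES))
    log.add("non_autosomal", (keep & step).sum())
    keep &= ~step

    with np.errstate(invalid="ignore"):
        mono = np.array(
            [
                np.nanmin(geno.dosages[:, j]) == np.nanmax(geno.dosages[:, j])
                for j in range(geno.n_variants)
            ]
        )
    log.add("monomorphic", (keep & mono).sum())
    keep &= ~mono

    hwe_p = hwe_pvalues(geno)
    step = hwe_p < params.hwe_p_min
    log.add("hwe", (keep & step).sum())
    keep &= ~step

    call_rate = 1.0 - np.isnan(geno.dosages).mean(axis=0)
    step = call_rate < params.call_rate_min
    log.add("call_rate", (keep & step).sum())
    keep &= ~step

    if "info_score" in geno.variants.columns:
        info = geno.variants["info_score"].to_numpy(dtype=float)
        step = info < params.info_min
        log.add("info_score", (keep & np.nan_to_num(step, nan=False)).sum())
        keep &= ~np.nan_to_num(step, nan=False)

    maf = geno.maf()
    step = maf <= params.maf_min
    log.add("maf", (keep & step).sum())
    keep &= ~step

    out = geno.subset_variants(keep)
    out.variants["maf"] = out.maf()
    out.variants["hwe_p"] = hwe_p[keep]
    out.variants["call_rate"] = call_rate[keep]
    return out, log


def compare_allele_freq(
    geno: GenotypeMatrix,
    ref_freqs: dict[str, float],
    dev_max: float = 0.13,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Drop variants whose alt frequency deviates from a reference panel.

    Variants absent from ``ref_freqs`` are kept and counted in the log.
    """
    obs = geno.alt_freq()
    keep = np.ones(geno.n_variants, dtype=bool)
    n_absent = 0
    n_removed = 0
    for j, v in enumerate(geno.variants["variant_id"]):
        ref = ref_freqs.get(v)
        if ref is None:
            n_absent += 1
            continue
        if abs(obs[j] - ref) > dev_max:
            keep[j] = False
            n_removed += 1
    log = FilterLog()
    log.add("freq_deviation", n_removed)
    log.add("absent_from_reference_kept", n_absent)
    return geno.subset_variants(keep), log


def kinship_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise relatedness from standardized genotypes (GRM off-diagonal).

    Dosages are centered by 2p and scaled by sqrt(2p(1-p)); a pair's
    estimate is the mean product of their standardized genotypes. On this
    scale duplicates/monozygotic twins score ~1 and full sibs ~0.5, so the
    0.80 default threshold flags duplicate-level relatedness.
    """
    p = geno.alt_freq()
    usable = (p > 0) & (p < 1)
    d = geno.dosages[:, usable]
    p = p[usable]
    z = (d - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    z = np.nan_to_num(z)
    return (z @ z.T) / z.shape[1]


def kinship_filter(
    geno: GenotypeMatrix, kinship_max: float = 0.80, seed: int = 0
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop one member of each related pair (transitively, one per group).

    Relatedness groups are connected components of the graph with edges at
    kinship > ``kinship_max``; a seeded RNG keeps one random member per
    group. Returns the filtered matrix and removed sample ids.
    """
    if geno.n_samples < 2:
        return geno, []
    k = kinship_matrix(geno)
    n = geno.n_samples
    adj = (k > kinship_max) & ~np.eye(n, dtype=bool)
    # union-find over related pairs
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(*np.nonzero(np.triu(adj))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri

    rng = np.random.default_rng(seed)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep = np.zeros(n, dtype=bool)
    for members in groups.values():
        keep[rng.choice(members)] = True
    removed = [geno.samples[i] for i in range(n) if not keep[i]]
    return geno.subset_samples(keep), removed


def genotype_pca(geno: GenotypeMatrix, n_components: int = 5) -> pd.DataFrame:
    """PCs of the column-standardized dosage matrix.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude loading is positive.
    Returns a samples x components frame (columns PC1..PCk) with the
    explained-variance fractions in ``DataFrame.attrs['explained_variance_ratio']``.
    """
    if np.isnan(geno.dosages).any():
        raise ValueError("genotype PCA requires complete (post-QC) dosages")
    d = geno.dosages
    sd = d.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.any():
        raise ValueError("no variants with non-zero variance")
    if n_components > min(geno.n_samples, int(usable.sum())):
        raise ValueError("n_components exceeds matrix rank bound")
    z = (d[:, usable] - d[:, usable].mean(axis=0)) / sd[usable]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            scores[:, k] *= -1
            vt[k] *= -1
    out = pd.DataFrame(
        scores,
        index=geno.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    var = s**2
    out.attrs["explained_variance_ratio"] = (var / var.sum())[:n_components]
    out.attrs["loadings"] = vt[:n_components]
    return out
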
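"""Permutation-based cis-eQTL mapping.

Per gene: all variants within 1 Mbp of the gene body are tested by linear
regression of (covariate-residualized) expression on dosage. A permutation
pass shuffles the residualized expression vector, records the strongest
association per permutation, and fits a beta distribution to those minima
so that the empirical p-value can be extrapolated beyond the permutation
count (the FastQTL/GTEx device). Gene-level multiple testing uses Storey
q-values with a fixed lambda; significant per-variant calls come from
gene-specific nominal thresholds obtained by inverting each gene's beta
fit at the genome-wide empirical threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import (
    AssocRecord,
    Covariates,
    ExpressionMatrix,
    GeneEqtlSummary,
    GenotypeMatrix,
)

__all__ = [
    "CisWindow",
    "QvalueParams",
    "residualize",
    "nominal_scan",
    "permutation_pass",
    "qvalues",
    "gene_thresholds",
    "map_cis",
    "summarize_catalogue",
]

CIS_WINDOW_BP = 1_000_000


@dataclass
class CisWindow:
    """Gene body extended 1 Mbp both ways; lower bound floored at 1."""

    gene_id: str
    chrom: str
    lo: int
    hi: int

    @classmethod
    def for_gene(
        cls, gene_id: str, chrom: str, start: int, end: int, window: int = CIS_WINDOW_BP
    ) -> "CisWindow":
        return cls(gene_id=gene_id, chrom=str(chrom), lo=max(1, start - window), hi=end + window)

    def variant_mask(self, variants: pd.DataFrame) -> np.ndarray:
        return (
            (variants["chrom"].astype(str) == self.chrom)
            & (variants["pos"] >= self.lo)
            & (variants["pos"] <= self.hi)
        ).to_numpy()


@dataclass
class QvalueParams:
    lambda_: float = 0.85
    fdr_threshold: float = 0.05


class CollinearityError(ValueError):
    pass


def residualize(rows: np.ndarray, covariates: Covariates) -> np.ndarray:
    """Project rows (k x n) onto the orthogonal complement of the design.

    The design is the covariate matrix plus an intercept. Rank deficiency
    raises an error naming the collinear columns.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    q_design = covariates.design()
    rank = np.linalg.matrix_rank(q_design)
    if rank < q_design.shape[1]:
        names = ["intercept"] + covariates.names
        bad = []
        cols_seen: np.ndarray | None = None
        for i in range(q_design.shape[1]):
            cand = q_design[:, : i + 1]
            if np.linalg.matrix_rank(cand) == (0 if cols_seen is None else cols_seen) + 1:
                cols_seen = (0 if cols_seen is None else cols_seen) + 1
            else:
                bad.append(names[i])
        raise CollinearityError(f"rank-deficient covariates; collinear columns: {bad}")
    q, _ = np.linalg.qr(q_design)
    return rows - (rows @ q) @ q.T


def _t_pvalue(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def _corr_to_p(r2: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p of the dosage t-test from squared partial correlation."""
    r2 = np.clip(r2, 0.0, 1.0 - 1e-16)
    t2 = df * r2 / (1.0 - r2)
    # regularized incomplete beta: survival of F(1, df) at t^2
    return special.betainc(df / 2.0, 0.5, df / (df + t2))


def nominal_scan(
    gene_id: str,
    dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    expression: np.ndarray,
    covariates: Covariates,
    tss: int | None = None,
    strand: str = "+",
    pre_residualized: bool = False,
) -> list[AssocRecord]:
    """Per-variant slope / t / p for the dosage term, covariate-adjusted.

    Implemented as correlation between residualized expression and
    residualized dosages with dof n - n_covariates - 2, which matches the
    full design-matrix t-test exactly. Zero-variance dosages after
    residualization are skipped.
    """
    n = expression.shape[0]
    n_cov = len(covariates.names)
    df = n - n_cov - 2
    if df < 1:
        raise ValueError("not enough samples for the covariate model")
    if pre_residualized:
        y_res = np.asarray(expression, dtype=float)
        g_res = np.asarray(dosages, dtype=float)
    else:
        y_res = residualize(expression[None, :], covariates)[0]
        g_res = residualize(dosages.T, covariates).T

    y_norm = np.linalg.norm(y_res)
    g_norm = np.linalg.norm(g_res, axis=0)
    records: list[AssocRecord] = []
    maf_col = variant_meta["maf"].to_numpy() if "maf" in variant_meta else None
    pos = variant_meta["pos"].to_numpy()
    vids = variant_meta["variant_id"].to_numpy()
    for j in range(g_res.shape[1]):
        if g_norm[j] <= 1e-12 or y_norm <= 1e-300:
            continue  # monomorphic-in-residual-space; skipped
        r = float(y_res @ g_res[:, j] / (y_norm * g_norm[j]))
        r = max(min(r, 1.0 - 1e-16), -1.0 + 1e-16)
        t = r * np.sqrt(df / (1.0 - r * r))
        slope = float(y_res @ g_res[:, j] / (g_norm[j] ** 2))
        se = slope / t if t != 0 else np.inf
        p = float(_corr_to_p(np.array([r * r]), df)[0])
        dist = 0
        if tss is not None:
            dist = int(pos[j]) - int(tss)
            if strand == "-":
                dist = -dist
        records.append(
            AssocRecord(
                gene_id=gene_id,
                variant_id=str(vids[j]),
                slope=slope,
                slope_se=abs(float(se)),
                t_stat=float(t),
                nominal_p=max(p, 5e-324),
                tss_distance=dist,
                maf=float(maf_col[j]) if maf_col is not None else float("nan"),
            )
        )
    return records


def _beta_mom(x: np.ndarray) -> tuple[float, float]:
    m, v = x.mean(), x.var(ddof=1)
    if v <= 0:
        return 1.0, 1.0
    c = m * (1 - m) / v - 1
    return max(m * c, 1e-3), max((1 - m) * c, 1e-3)


def fit_beta(minima: np.ndarray) -> tuple[float, float, bool]:
    """Maximum-likelihood Beta fit to permutation minimum p-values.

    Method-of-moments start; on optimizer failure fall back to the
    moment estimates (flagged via the returned ``converged`` boolean).
    """
    x = np.clip(minima, 1e-300, 1.0 - 1e-12)
    a0, b0 = _beta_mom(x)
    slx = np.log(x).sum()
    sl1x = np.log1p(-x).sum()
    k = x.size

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        return -( (a - 1) * slx + (b - 1) * sl1x - k * special.betaln(a, b) )

    try:
        res = optimize.minimize(nll, np.log([a0, b0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
        if res.success and np.all(np.isfinite(res.x)):
            a, b = np.exp(res.x)
            return float(a), float(b), True
    except (ValueError, FloatingPointError):
        pass
    return float(a0), float(b0), False


def permutation_pass(
    gene_id: str,
    dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    expression: np.ndarray,
    covariates: Covariates,
    perm_min: int = 1000,
    perm_max: int = 10000,
    seed: int = 0,
    adaptive: bool = True,
    tss: int | None = None,
    strand: str = "+",
) -> GeneEqtlSummary:
    """Adaptive permutation scheme with beta extrapolation.

    Expression and dosages are residualized once; permutations shuffle the
    residualized expression vector. After ``perm_min`` permutations the
    scheme stops as soon as >= 100 permutation minima lie at or below the
    observed minimum, else continues to ``perm_max``. A Beta(a, b) is fit
    by maximum likelihood to the permutation minima;
    ``perm_p_beta = BetaCDF(observed minimum)`` and the direct estimate
    ``(1 + hits) / (1 + K)`` is reported alongside.
    """
    rng = np.random.default_rng(seed)
    n = expression.shape[0]
    n_cov = len(covariates.names)
    df = n - n_cov - 2
    y_res = residualize(expression[None, :], covariates)[0]
    g_res = residualize(dosages.T, covariates).T
    g_norm = np.linalg.norm(g_res, axis=0)
    usable = g_norm > 1e-12
    records = nominal_scan(
        gene_id, g_res[:, usable], variant_meta.iloc[usable].reset_index(drop=True),
        y_res, covariates, tss=tss, strand=strand, pre_residualized=True,
    )
    if not records:
        return GeneEqtlSummary(gene_id=gene_id, n_cis_variants=0, best=None)
    best = min(records, key=lambda r: (r.nominal_p, r.variant_id))
    y_norm = np.linalg.norm(y_res)
    gm = g_res[:, usable] / g_norm[usable][None, :]
    r_obs = np.abs((y_res / y_norm) @ gm)
    r2_obs_max = float(np.max(r_obs) ** 2)

    minima_r2: list[np.ndarray] = []
    hits = 0
    total = 0
    while total < perm_max:
        k = min(perm_min, perm_max - total)
        perms = np.empty((k, n))
        for i in range(k):
            perms[i] = y_res[rng.permutation(n)]
        perms /= np.linalg.norm(perms, axis=1, keepdims=True)
        r2 = (perms @ gm) ** 2
        chunk_max = r2.max(axis=1)
        minima_r2.append(chunk_max)
        hits += int(np.sum(chunk_max >= r2_obs_max))
        total += k
        if adaptive and total >= perm_min and hits >= 100:
            break

    min_p = _corr_to_p(np.concatenate(minima_r2), df)
    p_obs = float(_corr_to_p(np.array([r2_obs_max]), df)[0])
    a, b, ok = fit_beta(min_p)
    perm_p_beta = float(stats.beta.cdf(p_obs, a, b))
    perm_p_beta = min(max(perm_p_beta, 5e-324), 1.0 - 1e-16)
    return GeneEqtlSummary(
        gene_id=gene_id,
        n_cis_variants=int(usable.sum()),
        best=best,
        beta_shape1=a,
        beta_shape2=b,
        perm_p_direct=(1.0 + hits) / (1.0 + total),
        perm_p_beta=perm_p_beta,
        n_permutations=total,
        beta_fit_converged=ok,
    )


def qvalues(
    pvalues: np.ndarray, params: QvalueParams | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with a fixed lambda.

    pi0 = #{p > lambda} / (m (1 - lambda)), capped at 1 and floored at
    1/m to stay positive; q via the standard monotone sweep.
    """
    params = params or QvalueParams()
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    lam = params.lambda_
    pi0 = np.sum(p > lam) / (m * (1.0 - lam))
    pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def gene_thresholds(
    summaries: list[GeneEqtlSummary],
    q: np.ndarray,
    fdr: float = 0.05,
) -> float:
    """Genome-wide empirical threshold -> per-gene nominal thresholds.

    p_t is the midpoint between the largest beta-extrapolated empirical p
    among significant genes (q <= fdr) and the smallest among
    non-significant genes; each gene's nominal cutoff is the inverse beta
    CDF of p_t under its own fit. Sets ``is_egene`` and
    ``nominal_threshold`` in place and returns p_t (NaN if no gene is
    significant).
    """
    perm_p = np.array([s.perm_p_beta for s in summaries])
    sig = q <= fdr
    for s, qv, is_sig in zip(summaries, q, sig):
        s.q_value = float(qv)
        s.is_egene = bool(is_sig)
    if not sig.any():
        warnings.warn("no significant genes; eVariant catalogue will be empty")
        return float("nan")
    top = float(np.max(perm_p[sig]))
    if sig.all():
        p_t = top
    else:
        p_t = 0.5 * (top + float(np.min(perm_p[~sig])))
    for s in summaries:
        if np.isfinite(s.beta_shape1):
            s.nominal_threshold = float(stats.beta.ppf(p_t, s.beta_shape1, s.beta_shape2))
    return p_t


def map_cis(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Covariates,
    window: int = CIS_WINDOW_BP,
    perm_min: int = 1000,
    perm_max: int = 10000,
    fdr: float = 0.05,
    lambda_: float = 0.85,
    seed: int = 0,
    adaptive: bool = True,
) -> tuple[list[GeneEqtlSummary], pd.DataFrame]:
    """Full cis scan: permutation pass, q-values, thresholds, catalogue.

    Per-gene permutation streams are derived from ``seed`` and the gene
    index so results do not depend on evaluation order. Returns the
    per-gene summaries and the significant-pairs catalogue (one row per
    significant gene-variant association).
    """
    tss_all = expr.tss()
    summaries: list[GeneEqtlSummary] = []
    gene_windows: list[np.ndarray] = []
    seed_seq = np.random.SeedSequence(seed)
    gene_seeds = seed_seq.generate_state(expr.n_genes) % (2**31)
    for i in range(expr.n_genes):
        grow = expr.genes.iloc[i]
        win = CisWindow.for_gene(grow["gene_id"], grow["chrom"], grow["start"], grow["end"], window)
        mask = win.variant_mask(geno.variants)
        gene_windows.append(mask)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            summaries.append(GeneEqtlSummary(gene_id=grow["gene_id"], n_cis_variants=0, best=None))
            continue
        summaries.append(
            permutation_pass(
                grow["gene_id"],
                geno.dosages[:, idx],
                geno.variants.iloc[idx].reset_index(drop=True),
                expr.values[i],
                covariates,
                perm_min=perm_min,
                perm_max=perm_max,
                seed=int(gene_seeds[i]),
                adaptive=adaptive,
                tss=int(tss_all[i]),
                strand=str(grow["strand"]),
            )
        )

    tested = [s for s in summaries if s.best is not None]
    if tested:
        p = np.array([s.perm_p_beta for s in tested])
        q, pi0 = qvalues(p, QvalueParams(lambda_=lambda_, fdr_threshold=fdr))
        p_t = gene_thresholds(tested, q, fdr=fdr)
    else:
        pi0, p_t = float("nan"), float("nan")

    pairs: list[dict] = []
    for i, s in enumerate(summaries):
        if s.best is None or not s.is_egene or not np.isfinite(s.nominal_threshold):
            continue
        idx = np.flatnonzero(gene_windows[i])
        grow = expr.genes.iloc[i]
        records = nominal_scan(
            s.gene_id,
            geno.dosages[:, idx],
            geno.variants.iloc[idx].reset_index(drop=True),
            expr.values[i],
            covariates,
            tss=int(tss_all[i]),
            strand=str(grow["strand"]),
        )
        s.significant = [r for r in records if r.nominal_p < s.nominal_threshold]
        pairs.extend(r.as_dict() for r in s.significant)

    catalogue = pd.DataFrame(
        pairs,
        columns=[
            "gene_id", "variant_id", "slope", "slope_se", "t_stat",
            "nominal_p", "tss_distance", "maf",
        ],
    )
    catalogue.attrs["pi0"] = pi0
    catalogue.attrs["p_t"] = p_t
    return summaries, catalogue


def percentage(numerator: int, denominator: int, digits: int = 1) -> float:
    """Share of ``numerator`` in ``denominator`` as a rounded percentage."""
    if denominator <= 0:
        return float("nan")
    return round(100.0 * numerator / denominator, digits)


def summarize_catalogue(
    summaries: list[GeneEqtlSummary],
    catalogue: pd.DataFrame,
    gene_annotation: pd.DataFrame | None = None,
) -> dict:
    """Headline catalogue numbers.

    eGene count and fraction, significant pair count, unique eVariants,
    share of eVariants regulating more than one eGene, per-biotype eGene
    fractions, and TSS-distance quartiles of each eGene's best variant.
    """
    n_genes = len(summaries)
    egenes = [s for s in summaries if s.is_egene]
    out: dict = {
        "n_genes_tested": n_genes,
        "n_egenes": len(egenes),
        "egene_fraction_pct": percentage(len(egenes), n_genes, 1),
        "n_significant_pairs": int(len(catalogue)),
    }
    if len(catalogue):
        per_variant = catalogue.groupby("variant_id")["gene_id"].nunique()
        n_unique = int(per_variant.size)
        n_multi = int((per_variant > 1).sum())
        out["n_unique_evariants"] = n_unique
        out["n_multigene_evariants"] = n_multi
        out["multigene_evariant_pct"] = percentage(n_multi, n_unique, 1)
    else:
        out.update(n_unique_evariants=0, n_multigene_evariants=0,
                   multigene_evariant_pct=float("nan"))
    if gene_annotation is not None and n_genes:
        ann = gene_annotation.set_index("gene_id")
        egene_ids = {s.gene_id for s in egenes}
        by_bio = {}
        for bio, sub in ann.groupby("biotype"):
            tested = [g for g in sub.index if g in {s.gene_id for s in summaries}]
            if not tested:
                continue
            k = sum(g in egene_ids for g in tested)
            by_bio[bio] = {
                "n_tested": len(tested),
                "n_egenes": k,
                "egene_pct": percentage(k, len(tested), 2),
            }
        out["by_biotype"] = by_bio
    dists = [abs(s.best.tss_distance) for s in egenes if s.best is not None]
    if dists:
        qs = np.percentile(dists, [25, 50, 75])
        out["best_evariant_abs_tss_distance_quartiles"] = [float(v) for v in qs]
    return out
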
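"""Expression normalization: counts -> cross-dataset analysis-ready matrix.

Pipeline order (enforced via the matrix state tag):

1. per-dataset TMM library-size factors and CPM conversion,
2. per-dataset expression filter (CPM > 1 in >= 10% of samples) and
   intersection of the expressed-gene lists across datasets,
3. merge, log2(CPM + 1), quantile normalization across samples,
4. parametric empirical-Bayes batch (dataset) adjustment,
5. sample-level PCA outlier flagging.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix

__all__ = [
    "tmm_factors",
    "cpm",
    "expression_filter",
    "log_quantile_normalize",
    "batch_adjust",
    "sample_pca_outliers",
]


def tmm_factors(
    counts: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values library-size normalization factors.

    The reference sample is the one whose upper quartile of count
    proportions is closest to the mean upper quartile. For every other
    sample the factor is 2 to the precision-weighted mean of gene-wise
    log2 ratios (M-values) after trimming ``trim_m`` of each M tail and
    ``trim_a`` of each A (abundance) tail. Factors are rescaled so their
    log-mean is zero.
    """
    counts.require_state("counts")
    y = counts.values
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with zero total counts")

    uq = np.array([np.quantile(y[:, k] / lib[k], 0.75) for k in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for k in range(y.shape[1]):
        if k == ref:
            continue
        factors[k] = _tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def cpm(counts: ExpressionMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """Counts per million on TMM-effective library sizes."""
    counts.require_state("counts")
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    lib = counts.values.sum(axis=0)
    values = counts.values / (lib * factors)[None, :] * 1e6
    out = counts.with_values(values, "cpm")
    out.tmm_factors = factors
    return out


def expression_filter(
    datasets: dict[str, ExpressionMatrix],
    cpm_min: float = 1.0,
    sample_frac: float = 0.10,
) -> tuple[list[str], pd.DataFrame]:
    """Genes expressed in every dataset.

    A gene is expressed within one dataset iff CPM > ``cpm_min`` in at
    least ``ceil(sample_frac * n_samples)`` samples. Returns the shared
    (intersection) gene list in the gene order of the first dataset, plus
    a per-dataset summary with expressed counts and the number of genes
    failing the intersection.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    expressed: dict[str, set[str]] = {}
    counts = {}
    for name, mat in datasets.items():
        mat.require_state("cpm")
        need = math.ceil(sample_frac * mat.n_samples)
        ok = (mat.values > cpm_min).sum(axis=1) >= need
        ids = mat.genes["gene_id"].to_numpy()
        expressed[name] = set(ids[ok])
        counts[name] = int(ok.sum())
    shared = set.intersection(*expressed.values())
    union = set.union(*expressed.values())
    first = next(iter(datasets.values()))
    shared_list = [g for g in first.genes["gene_id"] if g in shared]
    summary = pd.DataFrame(
        {
            "dataset": list(counts),
            "n_expressed": list(counts.values()),
        }
    )
    summary.attrs["n_shared"] = len(shared)
    summary.attrs["n_failing_intersection"] = len(union - shared)
    return shared_list, summary


def log_quantile_normalize(merged: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) then rank-wise quantile normalization across samples.

    After normalization every sample carries the identical sorted value
    vector (the per-rank mean across samples); tied values receive the
    mean of the tied quantiles.
    """
    merged.require_state("cpm", "log2cpm")
    x = merged.values
    if merged.state == "cpm":
        x = np.log2(x + 1.0)
    g, n = x.shape
    target = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for k in range(n):
        col = x[:, k]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(g, dtype=float)
        ranks[order] = np.arange(g)
        vals = target[ranks.astype(int)]
        # average target values within tied groups
        r_avg = rankdata(col, method="average") - 1
        ties = r_avg != ranks
        if ties.any():
            sorted_col = col[order]
            cum = np.concatenate([[0.0], np.cumsum(target)])
            # group boundaries of equal values in sorted order
            uniq, starts = np.unique(sorted_col, return_index=True)
            ends = np.append(starts[1:], g)
            group_mean = (cum[ends] - cum[starts]) / (ends - starts)
            idx = np.searchsorted(uniq, col)
            vals = group_mean[idx]
        out[:, k] = vals
    return merged.with_values(out, "quantile")


def batch_adjust(expr: ExpressionMatrix, batches: list[str] | None = None) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch correction.

    The classic two-step model: gene-standardize using pooled
    within-batch variance, estimate per-batch per-gene location and scale
    effects, shrink them toward batch-level normal / inverse-gamma priors
    by iterating the posterior equations, remove the shrunken effects and
    back-transform. With a single batch the data are returned unchanged.
    """
    expr.require_state("quantile")
    if batches is None:
        if expr.dataset is None:
            raise ValueError("no batch labels available")
        batches = expr.dataset
    labels = pd.Series(batches)
    if len(labels) != expr.n_samples:
        raise ValueError("batch labels must match samples")
    uniq = labels.unique()
    if len(uniq) == 1:
        return expr.with_values(expr.values.copy(), "batch_adjusted")
    groups = [np.flatnonzero((labels == b).to_numpy()) for b in uniq]
    for b, idx in zip(uniq, groups):
        if idx.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    x = expr.values
    g, n = x.shape
    n_b = np.array([idx.size for idx in groups], dtype=float)
    batch_mean = np.column_stack([x[:, idx].mean(axis=1) for idx in groups])
    grand_mean = batch_mean @ (n_b / n)
    resid = x.copy()
    for bi, idx in enumerate(groups):
        resid[:, idx] -= batch_mean[:, [bi]]
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    s = (x - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(s)
    for bi, idx in enumerate(groups):
        sb = s[:, idx]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        dm, dv = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * dv + dm**2) / dv if dv > 0 else 2.0
        b_prior = (dm * dv + dm**3) / dv if dv > 0 else dm
        gamma_star, delta_star = _eb_iterate(
            sb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior
        )
        adjusted[:, idx] = (sb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    values = adjusted * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    return expr.with_values(values, "batch_adjusted")


def _eb_iterate(
    sb: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    conv: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    n = sb.shape[1]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        sum2 = ((sb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def sample_pca_outliers(
    expr: ExpressionMatrix, sd_threshold: float = 6.0, n_components: int = 10
) -> list[str]:
    """Samples beyond ``sd_threshold`` SDs on any of the first PCs.

    PCA over samples (genes centered); flags only — removal is the
    caller's decision.
    """
    expr.require_state("quantile", "batch_adjusted", "log2cpm", "cpm")
    x = expr.values - expr.values.mean(axis=1, keepdims=True)
    u, sv, vt = np.linalg.svd(x.T, full_matrices=False)
    k = min(n_components, sv.size)
    scores = u[:, :k] * sv[:k]
    flagged = np.zeros(expr.n_samples, dtype=bool)
    for c in range(k):
        col = scores[:, c]
        sd = col.std(ddof=0)
        if sd == 0:
            continue
        flagged |= np.abs(col - col.mean()) > sd_threshold * sd
    return [s for s, f in zip(expr.samples, flagged) if f]
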
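"""Approximate-Bayes-factor colocalization for two association traces.

Given per-variant effect sizes and p-values for two genes over the shared
variants of their cis windows, each variant's evidence is summarized by a
Wakefield approximate Bayes factor; the five-hypothesis posterior (no
signal / gene-A only / gene-B only / two distinct signals / one shared
signal) is assembled from prior-weighted sums of the per-variant ABFs,
all in log space. PP(H4) is the probability that one shared causal
variant drives both genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["ColocPriors", "ColocResult", "wakefield_labf", "coloc_abf"]


@dataclass
class ColocPriors:
    """Per-variant prior probabilities and the prior effect variance.

    p1/p2: prior that a variant is causal for gene A / gene B alone;
    p12: prior that it is causal for both. ``prior_sd`` is the prior
    standard deviation of the standardized effect (W**0.5).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd: float = 0.15

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2, self.p12):
            if not 0 < p < 1:
                raise ValueError("priors must lie in (0, 1)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclass
class ColocResult:
    gene_a: str
    gene_b: str
    n_shared: int
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    no_overlap: bool = False  # H4 forced to 0: no shared variants

    def as_dict(self) -> dict:
        return {
            "gene_a": self.gene_a,
            "gene_b": self.gene_b,
            "n_shared": self.n_shared,
            "pp_h0": self.pp_h0,
            "pp_h1": self.pp_h1,
            "pp_h2": self.pp_h2,
            "pp_h3": self.pp_h3,
            "pp_h4": self.pp_h4,
        }


def wakefield_labf(z: float, v: float, w: float) -> float:
    """Log approximate Bayes factor for one variant.

    ``0.5 * (log(V / (V + W)) + z**2 * W / (V + W))`` with z the Wald
    statistic, V its sampling variance and W the prior effect variance.
    """
    if v <= 0 or w <= 0:
        raise ValueError("V and W must be positive")
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z * z * r)


def _labf_vector(
    slope: np.ndarray, nominal_p: np.ndarray, se: np.ndarray | None, w: float
) -> np.ndarray:
    """Per-variant log-ABFs; V from the SE when given, else reconstructed.

    Reconstruction follows the summary-statistic convention: z from the
    inverse normal of p/2 with the slope's sign, V = (slope / z)**2.
    Variants where reconstruction is impossible (z == 0) get NaN and are
    dropped by the caller.
    """
    slope = np.asarray(slope, dtype=float)
    nominal_p = np.asarray(nominal_p, dtype=float)
    if se is not None:
        se = np.asarray(se, dtype=float)
        z = slope / se
        v = se**2
    else:
        z_mag = -stats.norm.ppf(np.clip(nominal_p, 1e-300, 1.0) / 2.0)
        z = np.sign(slope) * z_mag
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (slope / z) ** 2
    out = np.full(slope.shape, np.nan)
    ok = np.isfinite(v) & (v > 0)
    r = w / (v[ok] + w)
    out[ok] = 0.5 * (np.log1p(-r) + z[ok] ** 2 * r)
    return out


def coloc_abf(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    priors: ColocPriors | None = None,
    gene_a: str = "gene_a",
    gene_b: str = "gene_b",
) -> ColocResult:
    """Five-hypothesis colocalization posterior for one gene pair.

    ``stats_a`` / ``stats_b`` need columns ``variant_id``, ``slope``,
    ``nominal_p`` and optionally ``slope_se``; the test runs on the
    intersection of their variant sets. A pair without shared variants
    gets PP(H4) = 0 and a sentinel flag (the remaining mass is put on H0
    by convention).
    """
    priors = priors or ColocPriors()
    a = stats_a.drop_duplicates("variant_id").set_index("variant_id")
    b = stats_b.drop_duplicates("variant_id").set_index("variant_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        return ColocResult(
            gene_a=gene_a, gene_b=gene_b, n_shared=0,
            pp_h0=1.0, pp_h1=0.0, pp_h2=0.0, pp_h3=0.0, pp_h4=0.0,
            no_overlap=True,
        )
    w = priors.prior_sd**2
    la = _labf_vector(
        a.loc[shared, "slope"].to_numpy(),
        a.loc[shared, "nominal_p"].to_numpy(),
        a.loc[shared, "slope_se"].to_numpy() if "slope_se" in a else None,
        w,
    )
    lb = _labf_vector(
        b.loc[shared, "slope"].to_numpy(),
        b.loc[shared, "nominal_p"].to_numpy(),
        b.loc[shared, "slope_se"].to_numpy() if "slope_se" in b else None,
        w,
    )
    ok = np.isfinite(la) & np.isfinite(lb)
    la, lb = la[ok], lb[ok]
    if la.size == 0:
        return ColocResult(
            gene_a=gene_a, gene_b=gene_b, n_shared=0,
            pp_h0=1.0, pp_h1=0.0, pp_h2=0.0, pp_h3=0.0, pp_h4=0.0,
            no_overlap=True,
        )

    lsum_a = special.logsumexp(la)  # log sum_i ABF_i^A
    lsum_b = special.logsumexp(lb)
    lsum_ab = special.logsumexp(la + lb)  # log sum_i ABF_i^A ABF_i^B

    lh0 = 0.0
    lh1 = np.log(priors.p1) + lsum_a
    lh2 = np.log(priors.p2) + lsum_b
    # H3: p1 p2 (sum_i A_i sum_j B_j - sum_i A_i B_i), in log space
    cross = lsum_a + lsum_b
    diff = cross + np.log1p(-np.exp(np.clip(lsum_ab - cross, None, 0.0)))
    if not np.isfinite(diff):  # all mass on the diagonal; clamp at zero weight
        diff = -np.inf
    lh3 = np.log(priors.p1) + np.log(priors.p2) + diff
    lh4 = np.log(priors.p12) + lsum_ab

    lw = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lw - special.logsumexp(lw))
    pp = pp / pp.sum()
    return ColocResult(
        gene_a=gene_a, gene_b=gene_b, n_shared=int(la.size),
        pp_h0=float(pp[0]), pp_h1=float(pp[1]), pp_h2=float(pp[2]),
        pp_h3=float(pp[3]), pp_h4=float(pp[4]),
    )
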
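"""Core in-memory containers shared by all pipeline stages.

Genotypes are held as a samples x variants dosage matrix (values in [0, 2],
NaN = missing pre-QC) with a per-variant metadata frame; expression as a
genes x samples matrix with per-gene annotation and an explicit
normalization-state tag so stages can refuse out-of-order input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed expression states, in pipeline order.
EXPRESSION_STATES = ("counts", "cpm", "log2cpm", "quantile", "batch_adjusted")

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


class PipelineStateError(RuntimeError):
    """An operation was applied to data in the wrong normalization state."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    Parameters
    ----------
    dosages
        float array, shape (n_samples, n_variants); entries in [0, 2] or NaN.
    samples
        sample identifiers, length n_samples.
    variants
        DataFrame indexed 0..n_variants-1 with at least columns
        ``variant_id, chrom, pos, ref, alt``; optional ``maf, info_score,
        call_rate, hwe_p``.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but dosage matrix has "
                f"{self.dosages.shape[0]} rows"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variant records but dosage matrix has "
                f"{self.dosages.shape[1]} columns"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency = mean(dosage) / 2."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, keep: list[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with annotation and a state tag."""

    values: np.ndarray
    genes: pd.DataFrame
    samples: list[str]
    state: str = "counts"
    dataset: list[str] | None = None  # per-sample dataset/batch label
    tmm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value matrix {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.state not in EXPRESSION_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        self.genes = self.genes.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise PipelineStateError(
                f"operation requires state in {states}, got {self.state!r}"
            )

    def tss(self) -> np.ndarray:
        """Transcription start site: gene start on '+', gene end on '-'."""
        start = self.genes["start"].to_numpy()
        end = self.genes["end"].to_numpy()
        plus = self.genes["strand"].to_numpy() == "+"
        return np.where(plus, start, end)

    def subset_genes(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            values=self.values[idx, :],
            genes=self.genes.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            state=self.state,
            dataset=None if self.dataset is None else list(self.dataset),
            tmm_factors=None if self.tmm_factors is None else self.tmm_factors.copy(),
        )

    def with_values(self, values: np.ndarray, state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            genes=self.genes.copy(),
            samples=list(self.samples),
            state=state,
            dataset=None if self.dataset is None else list(self.dataset),
            tmm_factors=None if self.tmm_factors is None else self.tmm_factors.copy(),
        )


@dataclass
class Covariates:
    """Samples x covariates design (without intercept; added by consumers)."""

    values: np.ndarray
    names: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.names)):
            raise ValueError("covariate matrix inconsistent with names/samples")

    def with_columns(self, extra: np.ndarray, names: list[str]) -> "Covariates":
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != len(self.samples):
            extra = extra.T
        return Covariates(
            values=np.column_stack([self.values, extra]),
            names=self.names + list(names),
            samples=list(self.samples),
        )

    def design(self) -> np.ndarray:
        """Design matrix with a leading intercept column."""
        return np.column_stack([np.ones(len(self.samples)), self.values])


@dataclass
class AssocRecord:
    """One variant-gene nominal association."""

    gene_id: str
    variant_id: str
    slope: float
    slope_se: float
    t_stat: float
    nominal_p: float
    tss_distance: int
    maf: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "variant_id": self.variant_id,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "t_stat": self.t_stat,
            "nominal_p": self.nominal_p,
            "tss_distance": self.tss_distance,
            "maf": self.maf,
        }


@dataclass
class GeneEqtlSummary:
    """Per-gene cis-scan result after the permutation pass."""

    gene_id: str
    n_cis_variants: int
    best: AssocRecord | None
    beta_shape1: float = float("nan")
    beta_shape2: float = float("nan")
    perm_p_direct: float = float("nan")
    perm_p_beta: float = float("nan")
    n_permutations: int = 0
    beta_fit_converged: bool = True
    q_value: float = float("nan")
    nominal_threshold: float = float("nan")
    is_egene: bool = False
    significant: list[AssocRecord] = field(default_factory=list)
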
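# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limitations of `eqtlkit`.

## Pipeline model

The pipeline estimates, per gene, whether common genetic variation
within 1 Mbp of the gene body shifts its expression, in a cohort pooled
from several recruitment sites.

**Genotype QC.** Input dosages (0–2, imputed) pass a fixed, logged filter
chain: autosomes only → monomorphic removal → exact Hardy-Weinberg test
p ≥ 1e-6 (on nearest-integer hard calls, since HWE is defined on genotype
counts) → call rate ≥ 95% → imputation info ≥ 0.3 → MAF > 1%. An optional
step removes variants whose alt-allele frequency deviates from a
reference panel by more than 0.13 (alt-frequency scale, orientation
stable). Relatedness is screened with the standardized-genotype
covariance (GRM off-diagonal), on which duplicates/monozygotic twins
score ≈ 1 and full sibs ≈ 0.5; the default cutoff 0.80 therefore removes
duplicate-level pairs, keeping one random member per connected group.
This scale was chosen deliberately: on the kinship-coefficient scale
(half the GRM value) a 0.80 cutoff could never fire. Genotype PCs come
from the SVD of the column-standardized dosage matrix; component signs
are fixed by making each component's largest-magnitude loading positive.

**Expression normalization.** Each dataset (site) is processed
separately: TMM factors (trim 30% of each M tail, 5% of each A tail,
precision-weighted mean, reference = sample with upper quartile closest
to the mean; matches edgeR to ~1e-6), CPM on effective library sizes,
and an expression filter CPM > 1 in ≥ ceil(10% of samples). Only genes
expressed in *every* dataset survive. The merged matrix is
log2(CPM + 1)-transformed, quantile-normalized across samples (ties get
the mean of tied quantiles), and batch-adjusted with the parametric
empirical-Bayes location/scale model (gene-standardize on pooled
within-batch variance; shrink per-batch per-gene effects toward
normal/inverse-gamma priors by iterating the posterior equations to
1e-4; remove and back-transform; matches sva::ComBat to ~1e-5). The
batch model carries no covariates — only the dataset label enters.
Sample outliers are flagged (not removed) beyond a configurable number
of SDs on the leading expression PCs.

**Cis scan.** Nominal associations use residualized correlation with
df = n − C − 2, which reproduces the full-design least-squares t-test to
1e-8 (a standing oracle test). The permutation pass shuffles the
residualized expression vector against fixed residualized dosages
(single residualization; permutations therefore ignore the tiny
covariate-respecting structure, the standard choice in large-cohort QTL
pipelines). Adaptive stopping: after 1,000 permutations, stop once ≥ 100
permutation minima lie at or below the observed minimum, else continue
to 10,000; a fixed-K mode is available. The Beta(α, β) fit to the
permutation minima is maximum likelihood (Nelder-Mead on log-parameters,
method-of-moments start; the moment estimates are used, flagged, if the
optimizer fails). For a window of M independent null variants the minima
follow Beta(1, M) and the fit recovers α ≈ 1 — the calibration check run
in the test suite.

**Multiple testing.** Storey q-values with fixed λ = 0.85:
π₀ = min(1, #{p > λ}/(m(1−λ))), floored at 1/m to stay positive, and the
standard monotone sweep. The fixed-λ estimator is unstable when the
number of genes is small and the signal fraction large (no p exceeds λ
⇒ π₀ collapses); the pipeline is intended for panels of ≥ ~100 genes
with a null majority, and the validation scenarios respect that.
The genome-wide empirical threshold p_t is the midpoint between the
flanking empirical p-values at the q = 0.05 boundary (degenerate cases:
all genes significant → the maximum; none → no catalogue, warned).
Per-gene nominal cutoffs invert the gene's own beta fit at p_t.

**Conditional signals.** Forward-only: rank 1 is the primary best
eVariant; each round adds all discovered signal dosages to the covariate
set and rescans; discovery continues while the minimum nominal p beats
the same gene-specific p_g from the primary pass (no re-permutation per
round, the literal forward procedure). Variants in perfect LD with an
existing signal are skipped in favour of the next-best candidate; a rank
cap of 10 (with warning) guards degenerate inputs. Earlier signals'
p-values are not re-estimated after later inclusions.

**Regulatory clusters.** eVariants regulating ≥ 3 eGenes are merged by
single-linkage along each chromosome with gaps strictly below 1 Mbp
(singleton clusters have width 1 bp). Every gene pair inside a cluster
is tested with the approximate-Bayes-factor colocalization model:
per-variant log-ABF = ½(log(V/(V+W)) + z²W/(V+W)) with prior effect
variance W = 0.15², V from the slope SE when available, otherwise
reconstructed from (slope, p) via the inverse normal. Hypothesis weights
are prior-weighted log-sum-exp sums (H3's cross-minus-diagonal term is
clamped at zero weight if floating error makes it negative). Pairs
without shared window variants get PP(H4) := 0 with a sentinel flag.
Genes join one co-regulated group when connected by PP(H4) ≥ 0.8 edges;
connected components are the default semantics, with an all-pairs
(clique) mode behind a flag since the grouping convention is genuinely
ambiguous. Heatmap row order comes from complete-linkage agglomeration
on distance 1 − H4.

**GWAS integration.** Trait tables are filtered to genome-wide
significance (p < 5e-8), pruned greedily per trait by dosage r² > 0.5
(most significant kept; ties broken by position then id; variants absent
from the genotype matrix pass through but are flagged), and intersected
with the catalogue. Slopes are re-signed to the risk allele (flip when
the risk allele is ref), giving an up/down direction per (trait, gene).
Enrichment is a two-sided Fisher exact test of eVariant status among
GWAS variants versus all analyzed variants (the comparison group
includes the GWAS variants, matching the published convention; a
subtracted variant is available).

## Synthetic-data generator

The generator emulates the features of a pooled bulk-tissue study that
the pipeline must survive, with planted truth for scoring:

- **Genotypes**: per block of `block_size` consecutive variants, a pool
  of `n_founder_haplotypes` founder haplotypes is drawn at target
  frequencies in `maf_range`; each sample receives the sum of two pool
  draws. This yields strong within-block LD, near-zero between-block LD,
  and realized MAFs equal to the target plus Binomial(n_haplotypes)
  founder noise (SD ≈ 0.1 at the default pool of 20) — tunable LD
  without external simulators.
- **Expression**: counts are a rounded exponentiated Gaussian,
  x = μ_g + βd + β₂d₂ + batch + covariate effects + ε, counts = ⌈e^x⌋.
  β is calibrated so the primary dosage explains `effect_r2` of the
  genetic-plus-noise variance on the log scale (batch shifts and
  covariate effects sit on top and are removed by the pipeline). The
  log-normal form keeps library sizes, TMM and CPM meaningful without
  full negative-binomial machinery; it does not model count overdispersion
  at low expression, which the pipeline does not depend on.
- **Layout**: genes sit on one synthetic chromosome with 2 Mbp spacing
  (isolated cis windows); cluster groups are laid out compactly
  (150 kbp between members) around one shared causal variant so the
  1 Mbp window and cluster merging are exercised.
- **Covariates**: age, sex, post-mortem interval with small per-gene
  effects; three recruitment sites with per-gene batch shifts
  (SD 0.3 log units by default).
- **GWAS tables**: a configurable fraction of rows reuses planted causal
  variants; the rest point at non-causal variants.

Default study conditions (300 samples in three sites, 200 genes with
half carrying cis effects at r² = 0.2, 4,000 variants in 20-variant
blocks) mirror the validated recovery scenario: the full pipeline recalls
essentially all planted eGenes at q < 0.05 with an empirical false-call
fraction at the nominal level, recovers both signals of two-causal genes,
and reassembles planted shared-signal triples as co-regulated groups.
What passing these tests does **not** show: behaviour under real LD
(haplotype blocks here are clean and rectangular), population structure,
low-count overdispersion, or allele-specific artefacts.

## Numerical choices

- p-values from squared correlations go through the regularized
  incomplete beta function (numerically exact in the far tail, where the
  naive t-survival route underflows); nominal p floored at 5e-324.
- Permutation streams derive per-gene from one `SeedSequence`, so results
  are independent of gene evaluation order and fully reproducible.
- Beta-fit inputs are clipped to [1e-300, 1 − 1e-12]; PP vectors are
  renormalized after log-sum-exp.
- Quantile-normalization tie groups average the target values of the
  tied ranks (deterministic).
- TMM trim fractions fixed at the canonical 30% / 5%; the expression
  filter uses strict CPM > 1 and a ceiling on the sample count.
- Report percentages use conventional half-up rounding at the stated
  number of decimals.

## Limitations

- Trans-eQTL, interaction eQTL and multi-tissue designs are out of scope.
- Conditional discovery is forward-only; no joint re-estimation of all
  signals (no fine-mapping).
- The colocalization model assumes at most one causal variant per gene
  per region — within-cluster allelic heterogeneity dilutes PP(H4).
- Phasing, imputation and ancestry assignment are upstream of this
  pipeline: it consumes already-imputed dosages.
- The fixed-λ π₀ estimator needs a reasonable number of null genes (see
  above); for very small panels an FDR on the empirical p-values
  directly would be more stable.
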
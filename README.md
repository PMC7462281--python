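# eqtlkit

A cis-eQTL mega-analysis toolkit for bulk-tissue studies that pool
samples from several recruitment sites: genotype and expression quality
control, cross-dataset normalization, permutation-based cis-eQTL mapping
with beta-approximated empirical p-values, Storey q-values, iterative
conditional discovery of independent signals, regulatory-cluster
detection via pairwise colocalization, and integration of trait-associated
(GWAS) variants with enrichment testing. A synthetic-data generator with
planted truth makes every stage testable end to end.

It is written for analysts running expression-QTL scans on a few hundred
samples (the motivating setting is a ~311-sample retina cohort pooled
from three study sites) who want the whole chain — from dosage VCF/TSV and
count matrix to eGene catalogue, independent signals, co-regulated gene
groups and GWAS overlap — as one reproducible, seeded pipeline.

## The method

For each gene *g* with expression *y* and each variant with dosage *d*
within 1 Mbp of the gene body, the nominal association is the *t*-test of
β in

    y = α + β d + Cγ + ε

with covariates *C* (age, sex, study site, post-mortem interval, first
five genotype PCs). Expression and dosages are residualized against *C*
once, so the scan reduces to a correlation test with
df = n − #covariates − 2 (exactly equal to the full-design *t*-test).

Gene-level significance uses the permutation scheme popularized by
FastQTL/GTEx: the residualized expression vector is permuted K times
(adaptive, 1,000–10,000), the minimum nominal p across the window is
recorded per permutation, and a Beta(α̂, β̂) distribution is fit to those
minima by maximum likelihood. The empirical p-value is then

    p_emp = BetaCDF(p_min_observed; α̂, β̂),

which extrapolates below the 1/(K+1) resolution of direct counting.
Gene-level FDR uses Storey q-values with fixed λ = 0.85
(π₀ = #{p > λ} / (m(1−λ))). A genome-wide empirical threshold p_t — the
midpoint between the largest empirical p among significant genes
(q ≤ 0.05) and the smallest among the rest — is inverted through each
gene's beta fit to give a gene-specific nominal cutoff
p_g = BetaInvCDF(p_t; α̂, β̂); all window variants with p < p_g form the
eVariant catalogue. Independent secondary signals are found by forward
conditioning: add the best signal's dosage to the covariates, rescan,
repeat while the minimum p beats p_g.

Variants regulating ≥ 3 eGenes are merged into regulatory clusters
(single-linkage, gap < 1 Mbp), and every gene pair within a cluster is
tested for a shared causal signal with Wakefield approximate Bayes
factors under the five-hypothesis colocalization model (H0 no signal, H1/H2
one gene only, H3 two distinct signals, H4 one shared signal; priors
p1 = p2 = 1e-4, p12 = 1e-5). Genes connected by PP(H4) ≥ 0.8 edges form
co-regulated groups. Trait-associated variants (p < 5e-8, LD-pruned at
r² > 0.5) are intersected with the catalogue and tested for eVariant
enrichment with Fisher's exact test; risk-allele-aligned slopes give the
direction of the expression effect.

## Worked example

```python
from eqtlkit import PipelineConfig, SimulationConfig, simulate_and_validate

cfg = SimulationConfig(n_samples=150, n_variants=2000, n_genes=40,
                       egene_fraction=0.5, effect_r2=0.25, seed=1)
report = simulate_and_validate(cfg, PipelineConfig(seed=1, perm_min=500,
                                                   perm_max=1000))
print(report["egene_sensitivity"], report["false_egene_fraction"])
```

prints

```
1.0 0.0498...
```

every planted cis effect (20 genes at r² = 0.25, n = 150) is recalled at
q < 0.05, and ~5% of the called eGenes carry no planted effect — the
nominal FDR level. `examples/` contains one short script per capability
(simulation + mapping, the permutation/beta machinery, colocalization
clusters, GWAS enrichment, file-driven runs); each prints the numbers it
computes and a line on what they mean. The same stages are exposed on a
shell via the `eqtlkit` command (`simulate`, `run-all`, `validate`).

The enrichment worked example

```python
from eqtlkit import enrichment_test
enrichment_test(65, 665, 403151, 8686883)
```

returns `pct_gwas=9.77`, `pct_all=4.64`, `odds_ratio=2.23`,
`p_value=2.93e-08` (identical to R's `fisher.test` on the same table).

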
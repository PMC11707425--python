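# idicss

Immune-driver independent component profiles and the **iDICss** risk score
for tumor expression cohorts.

## The problem

Only a minority of melanoma patients respond to immune checkpoint blockade,
and recurrent driver mutations (BRAF, NRAS, TP53, ...) are known to shape
the tumor immune microenvironment (TIME). This package implements a scoring
system that exploits that interplay: it extracts latent transcriptional
programs from bulk expression, keeps the immune-relevant ones, perturbs
their per-sample activities with driver- and immune-gene mutation status,
and distills the result into a prognostic / response-predictive gene
signature. It is aimed at computational oncologists who have a gene x
sample expression matrix, somatic mutation calls and survival/response
endpoints for a cohort, and want a reproducible risk score transferable to
validation cohorts.

## The method

1. **ICA decomposition.** The log-scale expression matrix *E* (genes x
   samples) is decomposed as *E* ≈ *S·W* by FastICA, where *S* holds gene
   loadings of *k* independent components and *W* the per-sample mixing
   weights. Loading columns are unit-variance with non-negative skewness so
   components are reproducible; multi-restart stability indices are
   available.
2. **Immune component selection.** Each component's top-loading genes
   (|z| > 3) are tested for over-representation in immune gene sets
   (hypergeometric, Benjamini-Hochberg over the whole component x set
   family) and for excess connectivity in a reference PPI network against
   degree-matched permutations. Components passing both (q < 0.05,
   p < 0.05) are the key immune components; a Jaccard crosstalk network
   summarizes their overlaps.
3. **iDIC profile.** Mutation impacts are projected through the loadings,
   `impact(c, s) = Σ_{g mutated in s} S[g, c]`, separately for a driver-gene
   list (*D*) and for the immune gene sets (*I*), each row z-scored. The
   profile blends them with one parameter λ ∈ [0, 1]:

   `iDIC(c, s) = W̃(c, s) + λ·D(c, s) + (1 − λ)·I(c, s)`,  λ = 0.7 default.

4. **Subgroups and signature.** Consensus k-means clustering (k = 2) of the
   profile defines clusterA (immune-cold) and clusterB (immune-hot);
   cluster-differential genes (rank-sum q < 0.05, |log2FC| ≥ 1) feed an
   L1-penalized Cox model whose cross-validated fit yields the signature.
   The score `iDICss(s) = Σ_g β_g·z_g(s)` is split at the training-cohort
   median into low/high risk, and the threshold is frozen for validation
   cohorts.
5. **Evaluation.** Kaplan-Meier/log-rank comparisons, Harrell's C,
   response AUROC, time-dependent AUC, a combinatorial survival-learner
   benchmark (penalized Cox family, stepwise Cox, random survival forest,
   boosting, survival SVM, SuperPC, PLS-Cox), simple single-gene/gene-pair
   comparator baselines, and a Spearman drug-sensitivity screen against
   cell-line IC50 panels.

A synthetic-cohort generator (`idicss.simulate`) plants all of this
structure — heavy-tailed sources, immune gene sets with PPI cliques,
mutation-component links, survival and response signal — so the whole
pipeline is testable without external data.

## Worked example

```python
from idicss import IDICssModel
from idicss.simulate import SimConfig, simulate_cohort

bundle, truth = simulate_cohort(SimConfig(seed=7))   # 2000 genes x 300 samples
model = IDICssModel(bundle=bundle, immune_sets=truth.immune_sets,
                    ppi=truth.ppi, driver_genes=truth.driver_genes,
                    k=10, n_perm=499)
results = model.fit(seed=7)
print(results.summary())
```

prints

```
iDICss model fit
========================================
components fitted (k):       10
key immune components:       3 (IC2, IC3, IC5)
lambda (driver vs immune):   0.70
subgroups (PAC 0.000):  clusterA n=149, clusterB n=151
candidate DE genes:          302
signature genes (nonzero):   18
risk threshold (median):     -0.2958
training C-index:            0.923
log-rank p (high vs low):    2.09e-64
response AUC (low=responder):0.833
```

Reading the output: the three planted immune components were selected
(IC2/IC3/IC5); consensus clustering split the cohort into the immune-cold
clusterA and immune-hot clusterB with a perfectly unambiguous consensus
matrix (PAC 0.000); the LASSO-Cox fit kept 18 genes; the resulting score
discriminates survival (C-index 0.923, log-rank p ≈ 2e-64 between the
median-split groups) and responders have lower scores (AUC 0.833 for
−iDICss). Validation cohorts
are scored with `results.predict_risk(expression)` using the frozen
threshold.

The same pipeline is scriptable from the shell:

```bash
idicss simulate --out simdata/ --seed 7
idicss fit --data simdata/ --k 10 --seed 7 --out fit/
idicss score --expr other_cohort.tsv --signature fit/signature.tsv --out scores.tsv
```

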
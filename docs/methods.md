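# Methods

This note documents the models, defaults and numerical choices behind
`idicss`, and what the synthetic cohorts do and do not establish.

## Model overview

The pipeline treats a bulk expression cohort as a linear mixture of latent
transcriptional programs and asks which programs describe the tumor immune
microenvironment (TIME), how somatic mutations perturb them, and whether a
compact gene signature derived from that perturbed profile predicts
survival and immunotherapy response.

### ICA decomposition

`fit_ica` double-centers the log-scale expression matrix (gene means, then
residual sample means) and runs FastICA (parallel extraction, logcosh
contrast, tolerance 1e-6, at most 1000 iterations) with genes as the
observation dimension: the source matrix *S* (genes x k) holds gene
loadings, the mixing matrix *W* (k x samples) per-sample weights, and
`E_centered ≈ S·W`. Identifiability requires non-Gaussian loading
distributions, which sparse biological programs satisfy (few strongly
loaded genes, heavy tails). Two conventions remove the permutation/sign
ambiguity within a run: every loading column is scaled to unit sample
variance (compensated in *W*), and flipped so its skewness is
non-negative. `k` defaults to 100 for real cohorts, where programs number
in the tens; all synthetic experiments use the generator's true `k = 10`.
Non-convergence is recorded on the result, not raised, because a
near-converged basis is still usable and the flag lets callers decide.

Stability (`stability_select`) refits with seeds derived from one base
seed and greedily matches components of the reference run to each restart
by absolute Pearson correlation of loading columns; the index is the mean
matched |r|. Correlation rather than a binned mutual-information estimate
keeps the statistic deterministic and free of bin-width choices; for the
linear, unit-variance loading columns the two orderings agree.

### Immune component selection

A component's gene signature is its top-loading genes, |z| > 3 within the
column — roughly the 0.1% tail of a Gaussian, the conventional cutoff for
ICA signatures. Two independent criteria must both hold:

* **Enrichment** — hypergeometric over-representation of the top genes in
  at least one immune gene set, with Benjamini-Hochberg correction over
  the *joint* component x set family (controlling FDR over the whole scan,
  not per component); selected iff best q < 0.05.
* **Connectivity** — the top genes share more PPI edges than degree-matched
  random gene sets. Nodes are binned into degree deciles and null sets
  sampled within bins, the standard correction for hub bias;
  p = (1 + #{null ≥ observed}) / (1 + n_perm) is never exactly zero and is
  valid at any n_perm. Default n_perm = 999 (499 in the large repeated
  experiments); selected iff p < 0.05.

The Jaccard crosstalk network over top-gene sets (edges at overlap ≥ 0.05)
is reporting/visualization output; selection never consumes its topology,
because no principled rule maps overlap structure to immune relevance and
the two tests above already encode the intended criteria.

### Mutation impact and the iDIC profile

For a gene set G the impact of sample s on component c is the sum of
loadings of the mutated set genes, `Σ_{g∈G, mut(g,s)=1} S[g,c]`, rows
z-scored across samples (zero-variance rows set to 0 so mutation-free
cohorts degrade gracefully). Two impacts are computed: *D* from the
user-supplied driver list and *I* from the union-free immune gene sets
("immunological mutations" read literally as mutations in immune-set
genes). The profile is the additive blend

    iDIC(c, s) = W̃(c, s) + λ·D(c, s) + (1 − λ)·I(c, s)

with W̃ the z-scored key-component weights. The blend is intentionally the
simplest form honoring the λ contract — λ trades driver against immune
mutation influence, λ = 1 ignores *I* exactly, and no mutations return W̃
exactly — and it is affine in λ with slope D − I, which makes the contract
checkable to machine precision. The formula carries a version tag
(`additive-v1`) so alternatives (e.g. multiplicative modulation) can be
added without ambiguity. λ defaults to 0.7 (driver mutations carry 70% of
the mutation influence); `IDICssModel.lambda_sensitivity` reports the
training C-index over a λ grid (0.5/0.7/0.8/1.0 by default) and leaves the
choice to the user.

### Subgroups

Consensus clustering: 250 k-means runs (k = 2) on random 80% sample
subsets; the consensus matrix is the co-assignment frequency among
co-sampled pairs; final labels cut an average-linkage tree of
(1 − consensus); quality is summarized by PAC, the fraction of off-diagonal
consensus entries in (0.1, 0.9). If the tree cut degenerates (fewer than k
leaves distinguishable) a single deterministic k-means supplies labels.
"clusterA" is anchored to the cluster with the lower mean immune signature
score (mean of gene-wise z-scored expression over the immune sets) so the
label is reproducible rather than arbitrary; without expression the larger
cluster is A.

### Differential expression and the signature

Cluster-differential genes use the two-sided Wilcoxon rank-sum test (exact
null when both groups have < 10 samples and no ties, else the
tie-corrected normal approximation), BH over all genes, candidates at
q < 0.05 and |log2FC| ≥ 1 (expression is already on the log scale, so the
fold change is a mean difference). The signature is an L1-penalized Cox
model on gene-wise z-scored candidates: the penalty path comes from
coordinate descent, and the penalty is chosen by 10-fold cross-validated
partial-likelihood deviance in the Verweij–van Houwelingen form (full-data
minus training partial log-likelihood, which is well-defined on small
held-out folds). The default rule takes the strongest penalty within one
standard error of the CV minimum: on planted cohorts the CV minimum
admits roughly twice as many spurious genes as true ones tolerate, while
the 1-SE rule retains all planted hazard genes with few extras; the CV
minimum remains available (`penalty_rule="min"`) for users who prefer
denser signatures. The signature size is a data-dependent outcome, never
forced. Scoring is `Σ_g β_g·z_g(s)` with z-scores computed within each
cohort — an explicit harmonization choice that makes the score invariant
to gene-wise affine platform differences when transferring to validation
cohorts. The median split is computed on the training cohort, ties go to
"low" (a fixed strict-inequality rule), and the threshold is frozen
thereafter.

### Evaluation

Harrell's C is implemented directly with the exact pair rules used
throughout (comparable pairs: earlier time is an event; ties in score
count 0.5; ties in time not comparable) and cross-checked against
lifelines in the tests. Response AUC is the Mann-Whitney statistic;
because low iDICss predicts response, response evaluations pass −score and
record the orientation. Kaplan-Meier curves and the log-rank test come
from lifelines; time-dependent AUC is the IPCW cumulative/dynamic
estimator with Kaplan-Meier censoring weights (horizons default to 1/3/5
years where follow-up allows). Classification metrics are reported at the
median-score operating point by default, with zero-denominator metrics
returned as "undefined" (None) rather than NaN.

The learner benchmark enumerates every registry adapter alone plus every
ordered (variable-selector, fitter) pair, trains on one cohort, fixes each
adapter's score orientation on the training data, and reports per-cohort
and average held-out C-index sorted descending. The catalogue size is a
function of the registered adapters, not a fixed number. Three adapters
are native approximations of R-ecosystem originals: CoxBoost ≈
componentwise gradient boosting of the Cox partial likelihood; SuperPC ≈
univariate-Cox screening + PCA + Cox on the leading components; PLS-Cox ≈
PLS regression on null-model deviance residuals followed by Cox on the
latent scores. Stepwise Cox is forward selection by partial-likelihood AIC
over a univariate prescreen (top 30) capped at 10 variables, which bounds
its cost on wide candidate sets.

The drug screen correlates the cell-line iDICss with per-drug IC50
(Spearman), BH over drugs, candidates at |ρ| ≥ 0.3 and q < 0.05, plus a
rank-sum comparison of IC50 between high/low score lines (median split).
Constant-IC50 drugs are flagged degenerate and never candidates.

## The synthetic cohorts

`simulate_cohort` emulates the statistical skeleton the pipeline assumes:
2,000 genes x 300 samples, 10 Laplace-loading components of which 3 are
immune (their ~60 top-loading genes drawn from emitted immune gene sets
and planted as cliques in a Barabási–Albert PPI backbone), 20 driver
genes, 10 risk genes with log-hazard ln 2 per expression SD (hazard ratio
2), exponential survival with independent exponential censoring at ~30%,
and Bernoulli response with logit decreasing in the true risk (slope 1.5),
so lower risk implies higher response probability.

The mutation layer encodes the method's central premise — driver mutations
shape the TIME. Each driver links to an immune component with probability
0.5 (otherwise to any component), its mutation log-odds follow the linked
component's weights (effect 1.5 per SD around a 15% base rate), and the
driver also receives a loading on that component signed like its link, so
the projected driver impact genuinely tracks component activity.
Immune-set genes mutate around an 8% background rate with log-odds
following their own component's weight oriented by their loading sign
(active, highly expressed programs accumulate detectable somatic
mutations), so the immune impact does too. Under this structure the
λ-blended profile reinforces, rather than dilutes, the planted regime
separation — the regime in which the blend is designed to operate. Two latent sample
regimes shift the immune components' weights by ±2 within-noise SDs
(`cluster_shift = 4`), a deliberately dichotomous immune-hot/cold
structure — the planted subgroups are meant to be well separated, and risk
genes also shift by 1.2 log-units between regimes (immune-hot = lower
risk), tying survival, response and subgroups together the way the method
presumes. Supplying a previous run's truth object regenerates only the
sample-level draws, yielding independent validation cohorts from the same
generative model.

What passing on these cohorts shows: the pipeline recovers planted
low-rank non-Gaussian structure, enrichment/connectivity signal, cluster
structure and proportional-hazards signal at realistic cohort sizes, with
calibrated nulls. What it does not show: robustness to platform/batch
artifacts, non-linear hazards, mutation signatures, correlated immune
programs that violate ICA independence, or the behavior of the published
comparator biomarkers — real-cohort replication is out of scope here.

## Numerical choices and degenerate inputs

* Duplicate gene rows: keep the highest-mean row. Missing expression:
  gene-wise median imputation before the zero-variance filter.
* Sample barcodes truncate to 15 characters (TCGA convention),
  configurable; survival is internally in days (months x 30.44 on input
  when declared).
* `ppi_connectivity_test` requires ≥ 2 query genes in the network and
  ≥ 100 permutations; components whose top genes fall below that are
  assigned p = 1 during selection rather than failing the scan.
* Rank-sum effect sizes are rank-biserial correlations; direction is the
  sign of the median difference.
* Empty LASSO models at the chosen penalty fall back to the densest path
  point so a signature always has ≥ 1 nonzero coefficient (the empty
  signature is unrepresentable by contract).
* All stochastic steps (ICA restarts, permutation nulls, consensus
  resampling, CV folds, simulation) consume explicit seeds; derived seeds
  come from a `numpy` Generator seeded once, and equal inputs with equal
  seeds reproduce outputs bitwise.

## Problem sizes

Tests and the acceptance script run at the generator's native scale
(2,000 x 300, 20-cohort repetitions for selection calibration, 499-999
permutations, 250 consensus resamples) with reduced-size cohorts only in
smoke tests of plumbing; the full suite and the acceptance run each finish
in a few minutes on one CPU.

## Known limitations

* The blending formula is one concrete realization of the λ framework;
  other couplings between mutation impact and expression weights are
  plausible and the version tag exists to host them.
* The exact-vs-asymptotic switch in the rank-sum test creates a small
  discontinuity in p-values at group size 10; families mixing both
  regimes are BH-corrected together regardless.
* Degree-decile matching controls first-order hub bias only; finer
  connectivity structure (clustering coefficient, community membership)
  is not matched.
* The R-learner approximations (CoxBoost, SuperPC, plsRcox) reproduce the
  families' inductive biases, not their exact fits; benchmark rankings
  involving them should be read accordingly.
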
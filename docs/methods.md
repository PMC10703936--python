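# Methods

This note records the statistical models, parameter defaults, numerical
choices and known limitations of `mddpipe`, in the order the pipeline
runs them.

## Synthetic cohort generator (`mddpipe.simulate`)

The generator emulates a multi-study postmortem brain RNA-seq
compendium of 216 control and 241 case samples spread over seven brain
regions (AnCg 24/23, aINS 22/26, Cg25 15/13, DLPFC 71/79, nACC 43/51,
OFC 22/25, vSUB 19/24).  For gene *g* and sample *s* the log2 mean is

    log2 mu_gs = a_g + log2 s_s + x_s . beta_g
                 + case_s * (lfc_{g, region(s)} + inf_g)
                 + sum_m loading_{g,m} * f_{s,m}

and counts are NB with Var = mu + alpha mu^2.  Components and defaults:

- **Baseline abundance** a_g ~ Normal(5, 2) on the log2 scale (median
  ~32 counts, spanning silent to highly expressed).  Planted DE genes
  may pin a_g (the default hub uses 7.0 ≈ 128 counts): the
  condition-associated genes of the emulated study are well expressed,
  and a gene at the detection floor could not have been the finding.
- **Library sizes** s_s ~ logNormal(0, 0.3): roughly ±35% depth
  variation, typical after within-study normalization.
- **Dispersion** alpha = 0.1 globally (Var = mu + 0.1 mu^2), a mid-range
  bulk-brain value.  A single global alpha keeps recovery tests tight;
  per-gene dispersion can be emulated downstream but is not generated.
- **Nuisance covariates**: source dataset (3 levels, uniform
  assignment), sex (female fraction 28.7% control / 42.7% case), age
  (Normal 47.66/46.78, sd ≈ 15.2, truncated at 0, years), PMI (Normal
  24.08/26.32, sd ≈ 16.2, truncated at 0, hours), region.  Per-gene
  effects for each covariate are drawn once from Normal(0, sd) with
  sd = 0.10 (dataset, region) and 0.05 (sex, age, PMI) in log2 units
  per level or per standardized unit — enough confounding that a design
  omitting them misbehaves, little enough that the design absorbs them.
- **Planted DE**: a hub gene at log2FC −1 in DLPFC, nACC and vSUB; an
  immediate-early-gene block (4 genes, −0.8, two regions); and
  region-specific genes with |log2FC| in [0.6, 2].  The study gives no
  effect-size distribution for real DE genes; this range is a declared
  free choice.
- **Co-expression modules**: two gene sets of 128 and 60 genes (the
  sizes the emulated analysis reported).  Members load (U(0.6, 1)) on a
  per-sample latent factor f ~ Normal(shift * case, 1.2) in log2 units;
  the condition shift (default −0.35) applies only in the three affected
  regions, so module activity separates the classes there and nowhere
  else.  The latent co-expression itself is global.
- **Pathways**: 30 sets of 20 genes.  Informative pathways (3 by
  default) are drawn first from the whole universe; decoys are drawn
  from the remaining genes so the planted label signal stays
  attributable (decoys may overlap each other).  Genes of informative
  pathways get an extra case shift of −0.3 log2 in all regions — weak
  enough that single genes rarely clear per-region DE thresholds, while
  the grouped signal is learnable by the kernel classifier, mirroring a
  study in which the classifier found pathway signal the regional DE
  did not.

Seeding: one root seed, with fixed child streams for pathways, metadata
and counts, so each stage regenerates independently and byte-identically.

**What the generator does not emulate**: gene-wise dispersion, gene–gene
correlation beyond the planted modules, isoforms, sex chromosomes,
region-specific expression programs, and read-level artifacts.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every failure mode of real tissue
data.

## Differential expression (`mddpipe.dge`)

- **Size factors**: median-of-ratios over genes positive in all samples,
  rescaled to geometric mean 1.  With no all-positive gene the caller
  must opt into a pseudocount.
- **Dispersions**: gene-wise method of moments on normalized counts,
  alpha_hat = max(alpha_min, (s2 − xi*ybar)/ybar^2) with s2 the
  OLS-residual variance against the design and xi = mean(1/s) the
  Poisson correction.  By default the log dispersions are shrunk halfway
  toward a fitted a + b/mean trend: the raw gene-wise estimates are
  noisy enough to inflate far-tail significance, and with shrinkage the
  family-wise discovery rate on null cohorts sits at the nominal 5%.
  This is a deliberately transparent stand-in for DESeq2's
  empirical-Bayes machinery; per-gene p-values will not match DESeq2.
- **GLM**: NB log-likelihood with log link and log-size-factor offsets,
  fitted by IRLS batched over all genes (they share the design matrix).
  Initialization: intercept at log normalized mean, other coefficients
  zero; linear predictor clamped to ±30 (natural log); convergence when
  max |delta beta| < 1e-6, at most 100 iterations; non-converged genes
  are flagged, excluded from the BH family and counted.  Covariance is
  (X'WX)^-1 at the final fit.  Coefficients are natural-log internally
  and reported as log2.
- **Design**: numeric covariates centered; categorical covariates
  treatment-coded with the lexicographically first level as reference;
  condition coded case vs control so downregulation is negative.  Rank
  deficiency raises an error naming the collinear columns (pivoted QR).
- **Testing**: Wald z with two-sided normal p; BH step-up over tested
  genes (NaNs excluded from m and propagated).  Genes with normalized
  mean below 1 are prefiltered before BH (a deterministic replacement
  for DESeq2's independent filtering); no fold-change cut-off.
- **A note on normalization invariance**: multiplying one library by c
  is absorbed exactly by its size factor, but no raw-count NB estimator
  can leave the Wald statistics bit-identical — a deeper library
  genuinely carries more likelihood information (the IRLS weight
  mu/(1+alpha*mu) is not scale-free).  The property tests assert exact
  absorption by the size factor and numerical stability (|dz| < 0.1) of
  the statistics.

Cross-region concordance uses Spearman correlation of log2FC over the
genes finite in both regions (NaN with a warning below 3 shared genes).
The intersection analysis reports per-region DE sets at padj < 0.05,
all intersection cardinalities, and the common set with per-region
log2FC signs.

## Co-expression (`mddpipe.coexpr`)

Input is log2(normalized counts + 1); the emulated analysis used
"normalized counts" without naming a transform, and log2+1 is fixed
here.  Pearson correlation is the default (the original tool's choice is
unstated); Spearman is available.

- **Variance filter**: statistic u = variance/mean of each gene's
  expression; null modelled as a scaled chi-square whose scale and df
  are fitted by quantile matching on the lower quartile and median
  (Brent root-find on df in [0.2, 5000]) so that a sizeable minority of
  genuinely variable genes cannot distort the null.  Genes with null
  p < 0.1 are kept; the threshold p >= 1 keeps everything.  On log
  expression u is abundance-dependent, so the filter favors genes whose
  excess variance beats the spread induced by the abundance
  distribution — the known behavior of variance filters of this family.
- **Soft threshold**: smallest beta in 1..20 whose connectivity
  distribution reaches scale-free fit R^2 >= 0.8 (log-log regression
  over 10 equal-width bins, R^2 zeroed for positive slopes); otherwise
  the best-fitting beta with a warning.
- **Modules**: adjacency |cor|^beta, topological overlap
  TOM_ij = (L_ij + A_ij)/(min(k_i,k_j) + 1 − A_ij), average-linkage
  clustering of 1 − TOM.  The cut height is placed, by default, in the
  largest gap of the dendrogram's merge heights on the log10(overlap)
  scale: module merges happen at overlap orders of magnitude above the
  noise band, and this gap is scale-free in beta, where any fixed height
  fails once beta grows.  If no gap spans a decade (no band structure,
  e.g. pure noise) a fixed 0.98 cut applies and everything stays
  unassigned.  Clusters below `min_module_size` (30 default, 10 in
  desk-scale tests) are unassigned.  Finally the usual
  eigengene-membership cleanup removes members with |kME| < 0.5
  (correlation with the module's first principal component), which
  strips chance-attached noise genes at low beta.
- **Class scores and NES**: genes are z-scored across all samples; a
  class's score per gene is the mean z over its samples (for two
  balanced classes the two rankings are exactly antisymmetric).  ES is
  the weighted KS running sum (hits advance by |score|/sum, misses
  retreat by 1/(N − N_hits); extremum by absolute value, ties to the
  earliest position; a set covering the whole universe scores +1 by
  convention).  The null is gene-label permutation: `n_perm`
  size-matched random sets on the same ranking (cheap, matches the
  gene-set null of standard GSEA; sample permutation is not used).
  NES = ES / mean |null ES of the same sign|; p is the signed tail
  (1 + #{|null| >= |ES|, same sign}) / (1 + #same sign); BH across
  modules within each class.

## Overrepresentation (`mddpipe.enrichment`)

One-sided Fisher exact p via the hypergeometric tail on the table
a = |query ∩ pathway|, b = |query| − a, c = K − a,
d = N − |query| − K + a; odds ratio (a·d)/(b·c) with Haldane 0.5 when a
cell is zero; BH across the collection.  The combined score is
−ln(p)·z with z the z-score of the pathway's p-rank under the real
query against its rank distribution over `n_resample` seeded random
queries of equal size, clipped at zero (so the score is non-negative, as
the reported tables imply); a cheaper log-odds-ratio mode is available
and documented as a different construction.  The background defaults to
the prefiltered count-matrix genes and is configurable — the web tool
behind the emulated tables uses an internal background that is not
public, so its scores are not reproducible quantity-for-quantity.  The
export includes the "k/K" overlap strings, the count of query genes
covered by no pathway, and gene–gene co-occurrence edges weighted by the
number of top-k pathways sharing both genes.

## MKL (`mddpipe.mkl`)

- **Preprocessing**: stratified 80/20 split (exact class ratios), log2,
  per-gene z-normalization fitted on the training partition only and
  applied unchanged to the test partition; a train-constant gene gets
  unit sd (and hence contributes nothing to train kernels — the leakage
  test in the suite).
- **Kernels**: Gaussian per pathway on its member genes, sigma^2 = mean
  squared pairwise training distance (a standard bandwidth heuristic;
  the original study defers kernel details to its computational
  reference, so this is a declared divergence).  Pathways with fewer
  than 3 expressed genes are skipped and recorded.
- **Weight optimization**: alternate (a) solving the soft-margin SVM
  dual on K_eta (scikit-learn SVC with precomputed kernel) and (b) the
  multiplicative simplex update eta_m ∝ eta_m sqrt(a' K_m a), wrapped
  in a geometric damping line-search that rejects steps increasing the
  min-max objective — the objective is therefore non-increasing by
  construction.  Entries below 1e-6 clamp to zero and stay zero;
  convergence at max |delta eta| < 1e-4 or 50 iterations (best iterate
  returned with a warning otherwise).  Two identical kernels keep equal
  weights (the update preserves symmetry).  Note that the converged
  optimum is sparse but not always a vertex: at weak regularization a
  tiny decoy weight can genuinely enlarge the training margin, so
  sparsity strengthens as C decreases.
- **Protocol**: per replication (child seed = root + index, recorded):
  split → 4-fold stratified inner CV over C in {0.01, 0.1, 1, 10, 100}
  (ties to the smallest C; degenerate folds are redrawn with a new
  seed) → final fit on the full training partition → Mann–Whitney AUC
  (ties 0.5) on the held-out samples.  Selection threshold 0.01 on
  eta; "informative" = selected in at least half the replications.
  Failed replications are excluded and counted.  Covariates are not
  given to the classifier; regions are pooled.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run everything on freshly
simulated cohorts: null DGE calibration on 50 (suite) / 20 (script)
replicates of 1,000 genes × 60 samples; hub recovery on 25 / 10
replicates of the full 457-sample seven-region cohort; module recovery
on 20 / 8 replicates of 1,000 genes × 200 samples with 30-gene modules
(latent sd 1.2, shift −0.6, moderate abundance spread so the variance
filter's null is informative); MKL on 20 / 10 outer replications of a
200-sample cohort with 3 informative pathways among 30, plus a
per-replication label-permutation control.  Exact-agreement oracle
checks cover BH (step-up brute force), Fisher p (hypergeometric pmf
sums over all backgrounds up to 25) and the GSEA ES (all subsets of a
12-gene universe).

## Known limitations

- Global NB dispersion in the generator; dispersion heterogeneity is
  only exercised through the estimator's own noise.
- The DGE stage is calibrated by simulation, not DESeq2-matched;
  outlier handling (Cook's distance) and LFC shrinkage are out of scope.
- The variance filter's abundance bias (above) means module recovery
  depends on module loadings exceeding the abundance-driven null
  spread.
- Enrichment combined scores depend on the configured background and
  resampling depth; rankings are stable across seeds at
  n_resample ≈ 2000 but individual z values are Monte Carlo estimates.
- MKL sparsity (and hence selection frequency) is a property of the
  regularized optimum, not a hard guarantee; heavily overlapping
  pathways share weight.
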
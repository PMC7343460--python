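# Methods

This note records the statistical model behind `agingphases`, the
algorithms and their parameters, why the defaults are what they are,
and the package's known limitations.

## 1. Data model

Two omics layers over a shared subject set, as features × subjects
matrices (`OmicsMatrix`):

- **expression**, working scale `log2_tpm` (`log2(TPM + 1)` from raw
  TPM);
- **methylation**, working scale `m_value`
  (`log2(beta / (1 - beta))`, betas clipped to `[1e-6, 1 - 1e-6]`
  before the logit so M values stay finite).

Matrices may carry a per-subject batch label. Gene sets use the GMT
format; linear clocks are stored as an intercept plus a named
coefficient vector with a declared input scale.

## 2. Preprocessing

1. **Scale transforms** as above (`transform_values`).
2. **Feature selection**: per-feature median absolute deviation (raw
   MAD, no consistency constant — only the ranking matters), keeping
   the top `ceil(0.10 · n_features)`; ties broken by feature id, output
   preserves input feature order (`mad_feature_select`).
3. **Batch correction**: parametric empirical-Bayes ComBat without
   covariates, delegated to `scanpy.pp.combat`. A single batch is an
   identity; batches with fewer than two subjects are rejected. Note
   that EB shrinkage leaves a small residual per-feature batch
   difference (tested at mean |Δ| < 0.1 for a 2-SD shift, n = 100 per
   batch); the refit batch location effect is ≈ 0.

Default order is select-then-correct; `preprocess_layer` can do
correct-then-select.

## 3. Similarity network fusion

For each preprocessed layer, pairwise Euclidean distance on
per-feature standardized values, then the scaled-exponential kernel

```
W_ij = exp(−d_ij² / (α · ε_ij)),   ε_ij = (knn_i + knn_j + d_ij) / 3
```

with `knn_i` the mean distance of subject i to its k nearest
neighbours, ε floored at 1e-12. Defaults `k = 10`, `α = 0.5`,
`t = 20` iterations (`SNFParams`).

Fusion follows the cross-diffusion scheme: a *status* matrix `P`
(off-diagonal rows normalized to sum ½, diagonal ½) and a *local* kNN
matrix `S` per layer; each iteration updates
`P_v ← S_v · mean(P_other) · S_vᵀ`, symmetrizes, and adds `I/n`. The
fused network is the mean of the final statuses, renormalized and
symmetrized — except at `t = 0`, which returns the exact average of
the initial status matrices (the final renormalization would otherwise
break that contract; see the decision ledger).

**Cluster number**: eigen-gap `λ_{K+1} − λ_K` of the normalized
Laplacian (eigenvalues ascending), maximized over K ∈ [2, 8]; ties
broken by a rotation-cost score (mean of 1/max_j ũ_ij² over the
row-normalized first-K eigenvector matrix, identity rotation) and then
by smaller K. **Clustering**: Ng–Jordan–Weiss spectral clustering
(row-normalized eigenvectors, k-means with 50 restarts, fixed seed).

## 4. Phases, clocks, outliers

Clusters are ordered into phases 1..K by median chronological age
(mean age, then label, as tie-breakers). Age–phase association uses
one-way ANOVA or Kruskal–Wallis. Linear clocks are applied after
transforming the matrix to the clock's input scale; missing clock
features are an error.

**Quartile outlier rule** (per phase, type-7 quantiles, requires ≥ 4
subjects): *young-like* iff `age > Q3` and `age − Q3 ≥ IQR/3`
(chronologically old, molecularly young); *old-like* symmetric below
Q1. Expected signature: young-like subjects have negative
clock-minus-chronological-age deviation, old-like positive. Group
contrasts use Welch t or exact rank-sum with Benjamini–Hochberg
adjustment; binary outcomes get an age-adjustable logistic model whose
result is flagged unreliable under separation.

## 5. Enrichment (PLAGE) and grouping ANOVA

Genes are z-scored across subjects (population SD; zero-variance genes
dropped with a warning). A set's activity is the first right singular
vector of its z-scored submatrix, sign-oriented to correlate
non-negatively with the set's mean z profile. When that dot product is
numerically zero (|dot| ≤ 1e-9 · ‖reference‖ — the singular vector is
orthogonal to the set mean) the sign would be floating-point noise, so
a deterministic fallback makes the first non-negligible loading
positive. `grouping_signal_anova` runs a per-set one-way ANOVA under
alternative subject groupings (e.g. discovered phases vs equal-size
age bins), BH-adjusted across sets within each grouping.

## 6. Gene-set predictivity and hallmark succession

A gene set's predictivity is the repeated stratified 5×5
cross-validated accuracy of a random forest restricted to the set's
genes with `mtry = set size`. Trying all features at every split makes
each tree ordinary bagged CART, so `_forest.BaggedTreeClassifier`
drives scikit-learn's Cython tree builder directly (≈ 4× faster than
`RandomForestClassifier` at these sizes, with a public
`DecisionTreeClassifier` fallback); statistical equivalence to
`RandomForestClassifier(max_features=None)` is asserted in the tests.

- `pathway_predictivity`: mean ± SD over replicate CV runs (different
  seeds); an optional label-permutation mode gives an explicit null.
  Chance on balanced K-class data is 1/K; the class-imbalance-aware
  chance is the majority-class proportion.
- `phase_stratified_predictivity`: one-vs-all accuracy per phase.
- `succession_clustering`: profiles are z-scaled per set and clustered
  by average-linkage hierarchical clustering; each set's *peak phase*
  is the argmax of its raw profile (earliest on ties). On cohorts with
  the three archetypes this recovers primary (peak 2) → secondary
  (peak 3) → integrative (peak 4).
- `predictivity_phase_contrast`: one-sided signed-rank test that
  predictivity rises between two phases, flagged low-power below 5
  paired replicates.

## 7. Transcriptional noise

Within-phase pairwise Pearson correlation of whole preprocessed
profiles. The phase-3 → phase-4 contrast is a one-sided rank-sum on
pair correlations, plus a subject-level guard (each subject's median
correlation to same-phase peers) because pairs sharing a subject are
not independent. Caveat established during validation: phase *signal*
alone shifts within-phase correlations (phase centroids differ in
norm), so a clean null for this test requires both equal residual
noise and no phase effects — see the exchangeable-null control in
`examples/05_transcriptional_noise.py`.

## 8. Longitudinal classifier

Feature selection: per layer, one-vs-rest Welch t over phases, rank by
(p, −|t|, id), union of the top 50 per contrast. Classifier: bagged
trees (default 1000) on the concatenated selected features of both
layers. Evaluation: repeated stratified 5×5 CV with feature selection
*inside* each fold, scored by the Hand–Till multiclass AUC (mean over
unordered class pairs of the two conditional AUCs; cross-checked in
tests against `roc_auc_score(multi_class="ovo")` and a brute-force
rank oracle). Follow-up samples are assigned phases and summarized as
a transition matrix, stable fraction, forward movers and (flagged)
backward transitions.

## 9. Synthetic cohort generator

`CohortConfig` defaults define the study conditions: n = 86 subjects,
ages uniform on [21, 76], biological age = chronological + N(0, 4²),
four phases as equal-width bins of biological age (clipped), 2000
genes / 4000 CpGs, nine informative gene sets of 20 genes (three per
archetype with per-phase activity vectors primary (.30, 1, .70, .20),
secondary (.15, .30, 1, .55), integrative (.20, .35, .65, 1)), effect
size 2.0 on both layers, 200 clock CpGs with linear biological-age
drift (slope SD 0.02 M/yr) whose inverse defines the shipped clock,
500 phase-patterned CpGs, two batches with additive N(0, 0.3²) shifts,
lognormal per-feature residual SDs (median 0.25 expression / 0.35
methylation, spread 0.30), and residual noise doubled in phase 4.

Why these choices:

- **Lognormal residual SDs** make the top-MAD tail enriched for
  informative features, as in real transcriptomes where age-regulated
  genes are high-variance.
- **Near-equidistant archetype vectors**: a chain-like centroid
  geometry (phase 1 ≈ 2, 3 ≈ 4) puts the dominant spectral cut at
  K = 2; the vectors above keep the four centroids separable at K = 4.
- **Phase-patterned CpGs**: with methylation as a pure linear age
  gradient the fused network carries the phases in one view only and
  eigen-gap selects K = 2/3; discrete epigenetic phase structure is
  required for fusion to help.
- **Doubled phase-4 noise** makes last-phase subjects mutually remote;
  keeping phase 4 a coherent cluster then requires its centroid
  contrast to exceed 3σ²p, which the defaults satisfy. At these
  settings a 50-seed study selects K = 4 in 98% of cohorts with
  phase-recovery ARI 1.0.

Follow-ups re-simulate the same subjects from the same latent model
with biological age advanced, so phases never move backward in truth.
`generate_null_sets` draws gene sets from the non-informative pool.

## 10. Problem sizes in tests and scripts

The library defaults keep the literature-scale parameters
(`n_trees = 1000`, full cohort sizes). Tests and `scripts/acceptance.py`
run the forests at 25–150 trees and fewer CV replicates: with
full-feature bagged trees the accuracy estimate is insensitive to tree
count far above ~50, so this is size scaling chosen for runtime (whole
suite ≈ 5 min, acceptance script ≈ 80 s on one CPU), not a change of
method or thresholds.

## 11. Limitations

- The generator is additive-Gaussian per feature (log/M scale) with
  batch shifts and phase means; it does not model count overdispersion,
  cell-composition drift, or feature–feature correlation beyond the
  shared phase/batch structure.
- ComBat is the parametric EB variant without biological covariates;
  residual batch differences of EB-shrunken magnitude remain.
- The rotation-cost score uses the identity rotation (no Givens-angle
  optimization); it serves only as an eigen-gap tie-breaker.
- `phase_stratified_predictivity` reports raw one-vs-all accuracy, so
  class imbalance inflates the baseline; profiles are z-scaled before
  succession clustering, which removes the per-set offset but not all
  imbalance effects.
- The noise contrast cannot distinguish "more residual noise" from
  "weaker shared signal" in the last phase; both lower within-phase
  correlation.
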
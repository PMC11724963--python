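# Methods

This note documents the models, estimators and numerical choices behind
`digicms`, and what the synthetic-data experiments do and do not establish.

## Problem setting

HPV-positive cervical squamous cell carcinoma separates into two consensus
molecular subtypes (CMS), C1 and C2, defined from expression/methylation
profiling; C2 carries the worse prognosis. Molecular subtyping is expensive,
so the package predicts the subtype from routine H&E whole-slide images.
Only patient-level labels exist, while the morphological correlates of the
subtype are localised, which makes this a multiple-instance learning (MIL)
problem: each patient is a *bag* of patch embeddings
{f₁ … f_K}, f ∈ ℝ¹⁰²⁴ (the output contract of a histology foundation
model), labelled Y ∈ {0 = C1, 1 = C2} at bag level only.

## Triplet-ranking MIL

A two-layer perceptron g: ℝ¹⁰²⁴ → ℝ (1024 → 512 → 1, ReLU) scores each
patch; the patch-level digital-CMS score is σ(g(f)) ∈ [0, 1] and the
patient-level score x is the arithmetic mean of patch scores. Training
minimises, over sampled triplets of one C2 bag (score x_p) and two distinct
C1 bags (x_n1, x_n2),

    L = [α₁ − (x_p − x_n1)]₊ + [α₁ − (x_p − x_n2)]₊ + [(x_n1 − x_n2)² − α₂]₊

with inter-class margin α₁ = 0.5 and intra-class bound α₂ = 0.1. The loss is
zero exactly when the C2 score exceeds both C1 scores by α₁ and the two C1
scores differ by at most √α₂. Optimisation is SGD, momentum 0.9, weight
decay 10⁻⁴, learning rate 3·10⁻³ decayed ×0.1 every 10 epochs, at most 20
epochs, one parameter update per sampled triplet.

Choices made where the method leaves freedom:

* **Score transform.** The loss is computed on sigmoid-transformed scores
  (patch scores are σ(logit), the bag score their mean). This keeps all
  scores in [0, 1], makes "probability of being C1/C2" language meaningful,
  and gives the aggregation the exact invariants (bounds, constants) the
  tests assert. Margins α₁ = 0.5/α₂ = 0.1 are commensurate with a score
  range of 1.
* **Triplets per epoch** = the number of labelled C2 bags in the training
  folds, so each C2 bag is seen once per epoch in expectation. Configurable.
* **Early stopping** monitors the mean triplet loss on the left-out fold
  with patience 3; the *saved* model is the epoch with the highest
  monitoring-fold AUC ("best-performing" read as discrimination, not loss).
* **Architecture** 1024 → 512 → 1 is a config knob; it is the default
  because it solves the synthetic task without being the bottleneck.
* The implementation is pure numpy with hand-derived gradients; all
  randomness (initialisation, fold split, triplet sampling) flows from one
  integer seed, so training is bit-reproducible.

### Cross-cohort protocol

Experiments use leave-one-cohort-out settings: the two training cohorts are
merged, split into three CMS-stratified folds; each fold model is trained on
two folds and monitored on the third; the fold model with the highest
monitoring AUC scores every patient of the held-out cohort. The Youden
cutoff is computed on the best model's merged-discovery scores, never on the
held-out cohort.

## Survival stratification

* **Cutoff**: Youden's J = sensitivity + specificity − 1, maximised over
  midpoints between adjacent distinct discovery scores plus ±∞; scores ≥
  cutoff are high-risk (predicted C2). Ties in J break toward the lowest
  threshold, assigning patients to high-risk only when forced.
* **Kaplan-Meier / log-rank** via lifelines (product-limit estimator;
  (k−1)-df chi-square log-rank).
* **Cox proportional hazards** via statsmodels `PHReg` with Breslow tie
  handling and Wald inference; categorical covariates expand against
  reference levels HPV16 / stage I / surgery (configurable). Perfect
  collinearity is detected by a rank check and reported rather than fitted.
* **C-index / DeLong**: Harrell's C over comparable pairs for survival
  endpoints; DeLong's test (midrank algorithm) compares two classifiers'
  AUCs against the binary CMS label, since DeLong is defined for AUCs, with
  Harrell's C reported separately. Zero estimated variance of the AUC
  difference (e.g. identical scores) returns p = 1 rather than dividing by
  zero.

## Exemplar mining

Per patient, the 20 patches scored most toward the patient's own subtype
(lowest scores for C1, highest for C2); per subtype group, k-means (k = 9,
k-means++, 10 restarts, fixed seed) on the patch embeddings; the exported
exemplar of each cluster is its medoid so that every exemplar is a real
patch. Score maps render patch scores as a diverging blue-red map centred at
the stratification threshold (the neutral colour marks the decision
boundary).

## Tumour-microenvironment profiling

For each region and cell type under one detector vocabulary (5-class
PanNuke-style or 6-class CoNIC-style, never merged): density ρ = N/A with A
in μm² (pixel area × mpp²), ln ρ, type ratio N_type/N_total, and
neutrophil-to-lymphocyte ratio (V6). Morphology per nucleus: polygon area
(shoelace × mpp²) and perimeter (edge sums × mpp), summarised as
mean/median/SD per type. Missing-value policy: ln ρ with N = 0, NLR with
zero lymphocytes and morphology of an absent type are *missing* (NaN), never
zero or infinite; such samples drop out of the affected feature's test only.
Tumour-rich lymphocyte density pools lymphocytes over 128 × 128 μm² grid
patches holding strictly more than 50 neoplastic nuclei (centroid
membership, half-open bins); zero qualifying patches yield a missing value.

Group comparisons per feature: Welch two-tailed t-test (primary), with
Mann-Whitney U (normal approximation, tie-corrected) and Cliff's delta
(positive = larger in C1) as distribution-free companions;
Benjamini-Hochberg across the tested feature family (one family per
vocabulary by default; configurable), significance at adjusted p < 0.05.
Spearman correlation (average ranks, t-approximation p) relates biological
features to digital-CMS scores.

**CD8 scoring**: H-DAB colour deconvolution (standard stain matrix,
scikit-image; the deconvolved channel is rescaled to OD₁₀ units), fixed DAB
threshold (default 0.15 OD, configurable — a conventional round value, as no
canonical threshold exists), positive fraction over the
saturation-thresholded tissue mask.

## Preprocessing

Tissue mask: bright desaturated pixels (V > 0.85, S < 0.15) and near-black
pixels (V < 0.1) are background; among the rest, Otsu's threshold on
saturation, capped at 0.25 so weakly stained tissue survives, floored at
0.05. Tiling: non-overlapping 256-px grid anchored at the origin at 0.5
μm/px; partial edge tiles are dropped so every patch has identical physical
area (keeping density denominators exact); a patch is kept only when its
tissue coverage *strictly exceeds* 0.8.

## Synthetic cohorts: what they emulate

The generator stands in for the external feature extractor, nuclei
detectors, scanner and registry:

* **Bags**: background patches ~ N(0, I₁₀₂₄); in each C2 bag,
  ⌈0.3·K⌉ patches are shifted by 2.0 (units of feature SD) along one fixed
  random unit direction shared by all cohorts. Defaults: 40 patients/class,
  K uniform in [96, 160]. The bag size matters: bag-mean noise along any
  axis scales as 1/√K, so very small bags make the task statistically
  harder than the whole-slide regime (where bags hold thousands of patches);
  [96, 160] is the smallest range that keeps the desk-scale task faithful
  to that regime. Ground-truth signal-patch indices are recorded, which is
  what permits the localisation tests.
* **Survival**: exponential event times, C1 hazard ln 2/1825 days (five-year
  median), C2 hazard ×2.0; independent exponential censoring calibrated to
  a 30 % censoring fraction. Closed forms make oracle expectations exact.
* **Nuclei**: Poisson counts per type at class-conditional densities
  (order 10⁻³ μm⁻², a few thousand nuclei/mm²); contours are 12-gons with
  jittered radii drawn from class-conditional normals. The default profiles
  encode the reported direction of subtype differences: more lymphocytes in
  C1; higher neutrophil ratio and NLR, and larger, more variable neoplastic
  nuclei, in C2.
* **IHC tiles**: stain concentrations built in OD space and mapped through
  the inverse H-DAB matrix, so the planted DAB-positive fraction is known
  exactly up to pixel quantisation.

What passing on synthetic data does **not** show: robustness to staining and
scanner variation across cohorts, to feature-extractor drift, to nuclei
mis-segmentation, or to non-exponential hazards — the generator draws all
cohorts from one latent distribution and only sample noise differs. Results
on real cohorts depend on those factors; the synthetic experiments verify
the estimators, the learning dynamics and the pipeline plumbing, not
clinical performance.

## Problem sizes and determinism

Default experiment sizes (40 bags/class, K ∈ [96, 160], 60 nuclei
regions/class, 200 log-rank null replicates, n = 500 Cox recovery) are
chosen so the full test suite and the acceptance script each complete in a
few minutes on one CPU while leaving comfortable statistical margins. Every
stochastic component takes an explicit seed; the pipeline derives per-stage
substreams from one config seed by hashing, so stages re-run in isolation
reproduce their outputs.

## Known limitations

* The MLP scorer is intentionally small and has no attention mechanism;
  patch scores are independent given the embedding.
* Single-permutation label-shuffle checks have heavy tails (residual class
  imbalance after shuffling is real signal of random sign); averaged
  replicates are used where a point estimate is reported.
* The Cox fit assumes proportional hazards and right censoring only; no
  competing risks or time-varying covariates.
* The tissue mask is a saturation heuristic; pen marks and blur are out of
  scope.
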
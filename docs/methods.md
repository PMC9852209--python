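# Methods

This note records the modelling assumptions, defaults, and numerical
choices behind `petsurv`, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

The pipeline addresses prognosis in amyotrophic lateral sclerosis (ALS) from
a single brain FDG-PET scan at diagnosis.  Survival time (PET to
death/tracheostomy) is treated as fully observed — censoring is not
modelled — and is discretized into a small number of prognostic profiles;
each profile is then characterised by the brain voxels that best preserve
the internal similarity structure of its patients, and a one-vs-all margin
classifier per profile predicts membership from those voxels.  Inputs are
assumed spatially registered to a common grid; registration, scanner
physics, and partial-volume/atrophy correction are out of scope.

## Synthetic cohort

No patient data ship with the package; the generator emulates the marginal
statistics of a 418-patient ALS cohort.

**Survival presets.**  Both presets share mixture weights (255, 124, 39)/418
over three classes supported on (0,2], (2,5], (5,∞) years.

- `marginal` draws each class from a piecewise-linear inverse CDF anchored
  so the pooled quartiles land on 0.61/1.45/3.27 years by construction
  (class 1 anchors (0,0), (0.41,0.61), (0.82,1.45), (1,2); class 2
  anchors (0,2), (0.4714,3.27), (1,5); class 3 is 5 + Exp(mean 2)).
- `clustered` draws compact profiles — truncated normal(1.0, 0.35) on
  [0,2], truncated normal(3.4, 0.5) on [2,5], 5 + Exp(mean 0.8) truncated
  at 8 — so that k-means recovers the classes with variance explained
  above 0.92.

The two presets are kept separate deliberately: a three-anchor calibration
cannot simultaneously match the pooled quartiles and deliver VE ≥ 0.92, so
one preset owns each property.

**Covariates.**  Sex, onset site, and King's stage follow class-conditional
multinomials taken from the emulated cohort's descriptive table (female
fraction rising with survival class, bulbar fraction falling, no King's 4 in
the long-surviving class); ages are truncated normals whose class means
decrease with survival class, encoding the older-age/shorter-survival
association.  The printed class-1 King's row (88, 74, 88, 11) sums to 261
rather than the class size 255; it is reconciled as (88, 74, 82, 11): the
stage-1 count 88 anchors the published odds ratio 0.52 and the stage-2/4
counts are kept as printed, leaving stage 3 the remainder.  The
stage-3/stage-4 cells are therefore approximate and are not used as
quantitative anchors.

**Phantom volumes.**  The default phantom is a 32×38×32 grid at 4 mm
(an ellipsoid "whole-brain" mask of ≈ 8040 voxels — desk-scale; the
91×109×91 full-resolution geometry is supported by configuration), with
background mean 1.0, voxel noise SD 0.05, and spherical lesions of radius
3.5 voxels and ±10% effect: class 1 carries one hypo- and one hypermetabolic
lesion, class 2 one hypermetabolic, class 3 two hypermetabolic — mirroring
the discriminant-cluster narrative of short survivors showing deep-grey
hypometabolism and longer survivors cerebellar hypermetabolism.  Lesion
centres are spaced so that smoothed lesions remain 26-disconnected.

Each subject carries a severity multiplier max(1 + 0.3·z, 0.2), z ~ N(0,1),
scaling all of their class's lesion effects.  This within-profile severity
gradient is what makes *unsupervised* within-class selection meaningful: with
a constant class offset, lesion voxels would be statistically
indistinguishable from background inside a class, and no within-class filter
could prefer them.  The default n_subjects = 150 (classes drawn from the
study weights) balances per-class graph sizes against runtime.

**What the phantom does not model.**  Scanner physics, attenuation,
reconstruction, registration error, anatomical variability, spatially
structured physiological noise, and any correlation between covariates and
image content.  Passing phantom tests therefore demonstrates correctness of
the algorithms under the stated generative assumptions, not clinical
performance on real scans.

## Preprocessing

Order: smooth (10-mm FWHM default), then intensity-normalize each masked
volume to whole-brain mean 1, then assemble the subjects × masked-voxels
matrix (row-major grid order; zero-variance columns retained and pushed to
the bottom of rankings downstream).  Smoothing order relative to
normalization is a convention (normalization rescales, smoothing is linear,
so the masked-smoothing result differs only through the mask-support
renormalization) and configurable via the pipeline.

Unmasked smoothing uses a symmetric ("reflect") boundary so total in-grid
intensity is conserved to machine precision.  When a brain mask is supplied
— as in the pipeline, whose volumes are zero outside the mask — smoothing is
confined to the mask and renormalized by the smoothed mask support.
Otherwise intensity bleeds across the brain boundary and, after whole-brain
normalization, interior voxels are biased several percent high — enough to
flip the apparent direction of a 10% hypometabolic lesion.  Kernels
narrower than half a voxel are bypassed (identity).

## Survival discretization

`kmeans_1d` computes the *exact* k-means optimum via an O(k·n²) dynamic
program over contiguous partitions (in 1-D every optimum is contiguous).
Restarted Lloyd iteration was rejected: at 20 restarts it demonstrably
misses the optimum on n = 200 instances, and the downstream quality checks
require exact agreement with the contiguous-partition optimum.  Ties in the
DP take the first (smallest-index) split; boundaries are midpoints between
adjacent cluster extremes and classes are numbered 1..k by ascending
survival.

`select_k` scores each k in 2..6 with the variance ratio
(SSB/(k−1))/(SSW/(n−k)) and picks the ratio's **first local maximum**
(falling back to the largest feasible k when the ratio is monotone).  The
raw ratio keeps creeping upward as the dense short-survival profile is
split, so its global maximum over-segments; the first peak is the standard
reading of "the ratio is maximal" for this criterion and recovers k = 3 on
clustered cohorts in 20/20 seeds.  Raw VE is reported for the chosen k
(≈ 93% at n = 418).  VE is undefined (error) when all times are equal; a
single-class labelling has VE = 0.

## Laplacian selection

Graph: symmetric union of directed 5-NN with heat-kernel weights; the kernel
width t defaults to the median squared kNN distance ("auto"), a scale-free
choice; duplicate subjects (all-zero distances) get unit weights.
Disconnected graphs are flagged, not rejected — a two-component graph is
legitimate (a feature constant within components scores 0, perfect
locality).

Scores are computed for all features at once by sparse products; columns are
pre-centred by their plain mean before the degree-weighted centring (a
mathematical no-op that eliminates the catastrophic cancellation which would
otherwise give constant features a spurious ~1e−33 denominator).  A feature
whose degree-weighted centred norm is ≤ 1e−12 of its scale gets a +inf
sentinel — flagged, never an exception, so bulk scoring proceeds — and ranks
last.  Ties break by ascending voxel index.  Lower score = better; a
configuration flag flips the direction for sensitivity analysis.  Defaults
m = 400 retained per class, with 2000 as a reported intermediate cutoff in
`score_profile`, whose "signal" measure is the inverse score (floored at
1e−12).

## Classification

Stratified 90/10 split with test size max(round(0.1·n), #classes) — the
floor lets stratification place at least one holdout subject per class.
Voxel selection runs on training rows only by default (no selection
leakage); the leaky variant (selection before the split) is available as an
explicit configuration switch for sensitivity analysis.  Per class, the
binary SVM (class_weight="balanced", to keep the rare long-surviving class
from being swamped) is tuned over kernel ∈ {linear, rbf, poly},
C ∈ 10^[−3,3], RBF γ ∈ 10^[−4,1], poly degree ∈ {2,3,4} to maximise mean
informedness over stratified 10-fold CV (folds are reduced when the rarer
class has fewer members; single-class folds are skipped with a warning).
The default search is sequential model-based: 10 random configurations, then
a Matérn-5/2 Gaussian-process surrogate with expected-improvement
acquisition over random candidate pools; `method="random"` gives plain
random search.  Budget defaults to 50 evaluations (desk scale; thousands are
supported by configuration).  Both searches are deterministic under the
seed.  After the search the winning configuration is refitted on all
training rows.

Holdout metrics per class: error rate (FP+FN)/n, informedness J from the
2×2 confusion, and the c-statistic computed as the tie-averaged rank AUROC
of the continuous decision values.  A class absent from the holdout is
flagged undefined rather than scored.  A K-NN one-vs-all baseline with the
same contract is optional.

## Cluster mapping

Connected components at 26-connectivity by default (the standard for
volumetric extent reporting; 6 and 18 available), keeping extents strictly
greater than 100 voxels.  Centroids are unweighted mean voxel coordinates
mapped through the affine; the peak is the cluster voxel with maximal
|mean relative intensity − 1| over the class's normalized scans
(score-weighted peaks were considered and rejected as less interpretable;
the intensity deviation is what the direction label is based on).
Direction: mean relative intensity < 1 → hypometabolic, ≥ 1 →
hypermetabolic (exact 1 counts as hyper).  Anatomical (atlas) labelling is
out of scope; reports carry voxel and mm coordinates only.

## Cohort statistics

Odds ratios are cross-products ad/(bc) with Woolf log-normal intervals at
z = Φ⁻¹(0.975) ≈ 1.959964 and no continuity correction by default — this
choice exactly reproduces the emulated cohort's published intervals
(0.35–0.78 and 1.13–2.63) from its table counts; Haldane–Anscombe +0.5 is
available by flag, and zero cells flag the estimate/interval undefined
instead of being corrected silently.  ANOVA is the classical one-way
decomposition.  Quantiles use linear interpolation (inclusive convention);
proportions are reported to one decimal.

## Pipeline & reproducibility

A single global seed fans out to per-stage sub-seeds by SHA-256 hashing of
"seed/stage", so any stage can be rerun in isolation.  Every run writes a
manifest (package version, config hash, seed); reruns with identical config
and seed are bit-identical.  Missing inputs fail pre-flight with the full
list of absent files.

## Problem sizes used in the shipped experiments

Tests and the acceptance script run at desk scale by choice: phantom
32×38×32 @ 4 mm with 150 subjects, search budgets of 50 (signal runs) and
10 with the random sampler (the 20-seed label-shuffle null, where search
sophistication is irrelevant under the null), and 20 repetitions of
n = 418 cohorts for the generator-calibration summaries.

## Known limitations

- Censoring, time-varying covariates, and survival regression are out of
  scope; the discretize-then-classify formulation is the point of the
  package, not a recommendation against survival models.
- The first-local-maximum k-selection rule, the graph defaults
  (5 neighbours, auto kernel width), and m = 400 are conventions; all are
  configurable, and conclusions about real data would need sensitivity
  analysis over them.
- The inverse-score "signal share" of `score_profile` is a coarse summary:
  on the default phantom the top-400 share is several times the uniform
  share but background scores decay gently, so mid-ranked features retain
  non-negligible inverse-score mass.
- Phantom classification is nearly noiseless by design (strong, compact,
  disjoint lesions); holdout metrics of 1.0 there say nothing about
  attainable accuracy on real cohorts.
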
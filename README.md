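# petsurv

Explainable survival profiling from brain metabolic images.

`petsurv` implements a white-box pattern-recognition pipeline for predicting
the survival-time range of ALS patients from a single brain FDG-PET scan, and
for showing *which* brain regions drive each prediction.  It is aimed at
researchers in neuroimaging-based prognosis who want every stage of such a
pipeline — cohort structure, voxel selection, classification, cluster
explainability — testable end to end without access to patient data: a
synthetic cohort/phantom generator reproduces the statistical structure of a
418-patient ALS cohort (survival median 1.45 y, IQR 0.61–3.27 y, three
prognostic profiles of sizes 255/124/39) and plants class-conditioned
metabolic lesions whose recovery can be verified against ground truth.

## The method

1. **Survival discretization.** Survival times t₁…tₙ are partitioned by exact
   1-D k-means (dynamic programming over contiguous partitions).  Partition
   quality is the variance explained, VE = SSB/SST with
   SST = Σᵢ(tᵢ − t̄)², SSB = Σ_c n_c(t̄_c − t̄)²; the number of profiles k is the
   first local maximum of the variance ratio (SSB/(k−1))/(SSW/(n−k)).
   On cohorts like the emulated one this yields k = 3 profiles — (0–2],
   (2–5], > 5 years — with VE ≈ 93%.
2. **Class-aware Laplacian-score voxel selection.** Within each survival
   class, subjects form a kNN similarity graph with heat-kernel weights
   W_ij = exp(−‖xᵢ−xⱼ‖²/t).  With degrees D and Laplacian L = D − W, each
   voxel feature f gets the score L_r = (f̃ᵀLf̃)/(f̃ᵀDf̃), where
   f̃ = f − (fᵀD1/1ᵀD1)1.  Low scores mark voxels that respect the class's
   internal similarity structure; the top-m (default m = 400) voxels per
   class are retained.
3. **One-vs-all classification.** Per class, a binary SVM on that class's
   voxels is tuned — kernel ∈ {linear, RBF, polynomial}, C ∈ [10⁻³, 10³],
   kernel parameters — to maximise mean 10-fold cross-validated
   informedness J = sensitivity + specificity − 1, by a Gaussian-process
   expected-improvement search (random search available).  Evaluation on a
   stratified 10% holdout reports per-class error rate, J, and the
   c-statistic (tie-averaged rank AUROC).
4. **Cluster explainability.** Each class's selected voxels are reduced to
   3-D connected components; components of more than 100 contiguous voxels
   are reported with centroid/peak coordinates and their metabolic direction
   relative to the whole-brain mean (hypo- vs hypermetabolic).
5. **Cohort statistics.** Descriptive summaries, one-way ANOVA of survival
   by group, and King's-stage × survival-class odds ratios
   OR = ad/(bc) with Woolf intervals exp(ln OR ± z√(1/a+1/b+1/c+1/d)).

## Worked example

```sh
python examples/02_discretize_survival.py
```

```
variance-ratio criterion per k:
  k=2:     1493.8
  k=3:     3983.7
  k=4:     3594.7
  k=5:     3853.0
  k=6:     4916.7
chosen k = 3
VE = 95.0%
boundaries (years): [2.09, 4.76]
profiles: ['(0-2]', '(2-5]', '> 5']
```

The criterion's first peak is at k = 3: three survival profiles with cut
points near 2 and 5 years emerge unsupervised, explaining 95% of the
survival variance in this draw.  On the phantom, voxel selection and
classification recover the planted structure
(`examples/03_select_voxels.py`, `examples/04_classify_profiles.py`):

```
class 1:  358 planted voxels, recall in top-400 = 1.00, best score = 0.0822
class 2:  179 planted voxels, recall in top-400 = 1.00, best score = 0.1734
class 3:  358 planted voxels, recall in top-400 = 0.97, best score = 0.1426

class   error%  informedness  c-stat  TP/FN/FP/TN
    1     0.00         1.000   1.000  8/0/0/7
    2     0.00         1.000   1.000  5/0/0/10
    3     0.00         1.000   1.000  2/0/0/13
```

and `examples/05_map_clusters.py` turns the selected voxels into a cluster
table (extent, mm coordinates, hypo/hyper direction) whose entries land on
the planted lesions with the planted signs.  The full pipeline is also
available from the shell:

```sh
petsurv simulate -o out --seed 0      # synthetic cohort + phantom volumes
petsurv fit -o out --seed 0           # preprocess, discretize, select, train, map
petsurv report out                    # consolidated summary
```

## Layout

- `src/petsurv/synthetic.py` — cohort presets, covariates, phantom volumes
- `src/petsurv/preproc.py` — NIfTI I/O, smoothing, normalization, features
- `src/petsurv/profiles.py` — exact 1-D k-means, VE, k selection
- `src/petsurv/laplacian.py` — similarity graphs, class-aware Laplacian scores
- `src/petsurv/classify.py` — split, informedness/AUROC, tuning, OvA SVMs
- `src/petsurv/clusters.py` — 3-D components, localization, direction
- `src/petsurv/cohort_stats.py` — odds ratios, ANOVA, descriptives
- `src/petsurv/pipeline.py`, `cli.py` — orchestration and the `petsurv` CLI
- `docs/methods.md` — modelling assumptions, defaults, limitations
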
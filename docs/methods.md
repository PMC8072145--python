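# Methods

`escprog` implements a combined histopathology + CT + clinical prognostic
analysis for resected esophageal squamous cell carcinoma (ESCC), together with
a synthetic cohort generator so that every stage is testable without patient
data. This note records the models, the defaults and why, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The analysis

### Pathology arm: PPCR features

Each whole-microarray image (nominally 6000×6000 px) is tiled into
non-overlapping 50×50 patches (14,400 per patient at full scale; trailing
remainder pixels are dropped). Patches from all patients are pooled, converted
to grayscale with Rec. 601 luminance weights, flattened, z-scored per pixel
dimension (zero-variance dimensions dropped), projected onto the leading
principal components, and clustered with k-means into k clusters (default
k = 20 at full scale; the test-scale profile uses k = 8). The
pathological-patches-cluster-ratio (PPCR, also written PCPR) vector of a
patient is the fraction of their patches assigned to each cluster — a point on
the k-simplex summarizing tissue composition. Clusters are reported 1-indexed
("Cluster 1 … Cluster k") and 0-indexed internally.

Choices the literature leaves open, fixed here:

* **Patch representation** fed to PCA: grayscale flattened raw intensities.
  Deterministic and assumption-free; alternative descriptors can be plugged in
  before `fit_cluster_model`.
* **Number of components**: the smaller of 50 and the count reaching 95%
  explained variance (both configurable). Bounded cost, standard practice.
* **K-means**: seeded k-means++ with 10 restarts, 300-iteration cap,
  tolerance 1e-4 — for reproducibility, not performance.
* **Vocabulary scope**: fitted pooled over all patients, mirroring a pooled
  retrospective analysis. This leaks unsupervised information across
  cross-validation folds; for a leakage-safe variant refit the vocabulary
  inside each fold (the library functions compose freely).
* **No stain normalization**: none is applied by default; grayscale conversion
  is the only color handling.

### CT arm: radiomic features

3D features are computed from an intensity volume and a binary region-of-interest
(ROI) mask, from scratch, following IBSI-style definitions. The core registry
holds 105 named features in six classes — 3D shape (16), first-order (19),
GLCM (24), GLRLM (16), GLSZM (16), GLDM (14) — plus the 5-feature NGTDM class
as an explicitly flagged addendum (it is selected in practice, e.g.
`original_ngtdm_Contrast`, but sits outside the 105-feature core count). The
canonical mesh/moment shape set has 14 entries; the registry pads it with the
two legacy compactness variants to honor the 16-feature class size, and the
padding is explicit in `radiomics.registry`.

Conventions (all recorded in the extractor's JSON metadata):

* **Discretization**: fixed bin width 25 intensity units, min-referenced
  (`level = floor((I − min)/w) + 1`) — a common CT default; configurable.
* **Directions**: co-occurrence and run-length statistics are computed per
  direction over the 13 unique 3D offsets at distance 1 and features are
  averaged over directions.
* **Connectivity**: 26-connectivity for size zones, dependencies and NGTDM
  neighborhoods. Dependence counts include the center voxel (j = neighbors+1);
  the GLDM tolerance α defaults to 0.
* **Surface mesh**: marching cubes on the occupancy field after Gaussian
  anti-aliasing (σ = 0.7 voxel). Meshing the raw binary mask inflates surface
  area by ≈9% through staircase facets, biasing sphericity of a radius-20
  digital ball to ≈0.91; with anti-aliasing the same ball measures ≈0.987.
  Tiny/thin ROIs that would smooth below the iso level fall back to the raw
  mask mesh. Mesh volume uses the divergence theorem; surface area the summed
  triangle areas.
* **Axis lengths** are `4·sqrt(λ)` of the covariance eigenvalues of foreground
  voxel centers in mm; maximum 2D diameters are the largest pairwise
  surface-vertex distances after dropping one axis (the feature name states
  the dropped axis).
* **Undefined values** (e.g. GLCM correlation on a constant ROI, any
  co-occurrence feature on a single-voxel ROI) are emitted as NaN and listed
  in the result's `missing` field — never silently zeroed or imputed.
  Downstream, the feature-table builder drops columns that are undefined for
  any patient.
* **No resampling** to isotropic voxels by default (the generator produces
  isotropic grids); volumes with anisotropic spacing are handled through the
  spacing-aware mesh and coordinate computations.

### Feature selection

A univariate Cox model per z-scored feature screens at two-sided Wald
p < 0.2 (univariate fits via lifelines; HR, p and 95% CI reported per
feature). Zero-variance and non-converging features are flagged and excluded.
Recursive feature elimination then runs independently within each block (CT /
pathology / clinical): repeatedly fit a ridge-stabilized multivariable Cox
model (L2 = 0.1) on standardized features and drop the smallest-|coefficient|
feature, breaking ties toward the lexicographically last name, until the
per-block target is reached. Reference targets are CT = 8, pathology = 5,
clinical = 4 (a 17-feature combined list); on small synthetic cohorts the
screen can leave fewer, in which case targets clamp with a warning, and a
block emptied by the screen keeps its single smallest-p feature so every
model remains estimable. A `"auto"` target instead picks the count maximizing
LOOCV concordance along the elimination path (much slower). Screening and RFE
are invariant to feature column order.

### Survival modeling

The estimator maximizes the Breslow-ties Cox partial log-likelihood minus an
L1 penalty, `−(1/n)·l(β) + λ·Σ|β_j|`, on z-scored features by iteratively
reweighted least squares with cyclic coordinate descent and soft-thresholding
(the glmnet construction with diagonal Hessian weights). Convergence is
declared at max coefficient change < 1e-6 (cap 10,000 cycles). Two
numerical guards matter in practice:

* With exactly collinear columns (common among radiomic size features) the L1
  optimum is non-unique and the coefficient vector can wander or cycle at
  constant objective; a relative objective plateau (< 1e-10) and a
  sweep-stall detector terminate these cases, and a stalled solution whose
  remaining change is negligible on the coefficient scale is accepted with a
  warning.
* At λ = 0 (and for the RFE ridge fits) each IRLS quadratic is solved exactly
  by linear algebra instead of coordinate descent, which is far more robust
  under collinearity. The λ = 0 fit matches an independent Newton-type
  Breslow implementation to ~1e-7.

**Penalty selection**: 50 log-spaced values from λ_max (the smallest penalty
zeroing all coefficients, computed from the score at β = 0) down to
0.001·λ_max (0.01 when p ≥ n, the usual high-dimensional convention), chosen
by 5-fold cross-validated Verweij–van Houwelingen partial-likelihood deviance
`−2[l_all(β_train) − l_train(β_train)]` with seeded folds; ties resolve to the
larger penalty. Path fits inside cross-validation run at tolerance 1e-4 —
only their deviance is consumed, and 1e-4 coefficient error is far below its
fold-to-fold noise. Ties in the partial likelihood use Breslow's
approximation; the generator produces continuous (tie-free) times, where
Breslow and Efron coincide.

**Scores and stratification**: the survival score is SC = x'β on standardized
features; patients split at the cohort median of SC (scores equal to the
median go to the low-risk group — a deterministic tie rule). If the model
shrinks to the empty set, all scores are equal and a single low-risk group is
reported with a warning rather than an arbitrary split.

**Validation**: Harrell's C by exhaustive pair counting (comparable pairs:
strictly shorter time with an event; score ties count 1/2). LOOCV refits the
entire chain — standardization, penalty selection, LASSO-Cox — on each n−1
subset, scores the held-out patient, and computes a single C on the pooled
out-of-fold scores (per-fold C is undefined for singleton folds). Unfittable
folds are skipped with a warning and counted. Feature *selection* is not
repeated inside LOOCV, matching the pooled retrospective design this
pipeline implements; this is
a known optimism source and the fold-safe composition is available through
the library.

**Reports**: four nested models — clinical; CT+clinical; pathology+clinical;
combined — are evaluated on identical data and seeds. Kaplan–Meier curves
(lifelines) summarize each risk group with overall survival at 12 and 36
months and the median survival time (absent when the curve never reaches
0.5); the two-group log-rank test supplies the stratification p-value. No
inferential p-value is attached to C-index *differences* between models; the
reports print the C values themselves.

## The synthetic cohort generator

The generator is the study-conditions stand-in for a private surgical cohort
(~150 patients, median follow-up 28 months). Defaults:

* **Histology**: each patient's patch-class mixing is Dirichlet(1) over 6
  texture classes; a patch draws its class i.i.d. from the mixing. Classes are
  separable by construction — distinct Rec. 601 luminance targets spread over
  [40, 220] at the `easy` setting ([100, 160] at `hard`) with fixed hue
  palettes, a class-specific spatial frequency with random phase, and
  Gaussian pixel noise (σ = 8).
* **CT**: one axis-aligned rasterized ellipsoid per patient with semi-axes
  drawn uniformly per axis (full scale 5–18 / 4–14 / 3–10 mm), lesion mean
  100 over a background of 30, stationary correlated texture inside the
  lesion (per-case correlation length 0.5–2 voxels).
* **Clinical**: independent binary covariates with prevalences matching the
  emulated cohort (drinking 0.418, CRP class 0.307, AGR class 0.373, plus
  sex/age/smoking), and a 6-level ordinal TNM stage.
* **Survival**: exponential event times with rate `(ln 2 / 30)·exp(x'β)` per
  month on z-scored ground-truth features — so the median event time of an
  average patient is 30 months, near the emulated median follow-up — censored
  by the minimum of an exponential clock (rate 0.015/month) and a 60-month
  administrative horizon. The default β loads on all three blocks:
  two mixing proportions (+1.0, −0.7), log lesion volume (+0.8), TNM (+0.6)
  and CRP (+0.4). The exponential baseline is a sampling convenience; the
  pipeline never assumes it.
* All randomness derives from a single master seed through named substreams
  (one per patient per artifact type), so cohorts are bit-reproducible and
  partial regeneration is stable.

**What passing tests show — and don't.** The generator's textures are
separable by construction and its hazard is exactly proportional; recovery of
planted mixing (mean absolute error ≤ 0.05 over 20 patients) and the
qualitative model ordering (combined > clinical LOOCV C in ≥ 8/10 replicates)
demonstrate that the pipeline's machinery is correct and unbiased under its
own assumptions, not that real H&E texture clusters map onto cell types or
that real ESCC hazards are log-linear in these features. The generator omits
stain physics, nucleus-level morphology, correlated clinical covariates,
non-ellipsoidal lesion shapes and informative censoring.

## Problem sizes

The shipped test-scale profile uses 600×600 px images (144 patches each),
32³ CT volumes and cohorts of 20–40 patients; the full-scale profile
(6000×6000, 64³, k = 20, n ≈ 150) is the same code with different
configuration. The acceptance script analyzes a 40-patient cohort end to end,
runs the 10-replicate model-ordering comparison and a 10-seed null
calibration, all on one CPU in a few minutes.

## Known limitations

* Pooled vocabulary and pooled feature selection are optimistic relative to
  fully nested cross-validation (deliberate, to match the pooled design;
  see above for the fold-safe alternative).
* The exact feature-name lists for the shape-16 and first-order-19 classes are
  a documented choice (`radiomics.registry`), not an external ground truth.
* GLCM/GLRLM direction aggregation averages features over directions; other
  tools also offer merged-matrix aggregation, which gives slightly different
  values.
* Wald confidence intervals from single-covariate Cox fits are reported as
  conventional; no finite-sample correction is applied.
* The log-rank p-value is asymptotic (χ², 1 df) and unreliable for very few
  events.
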
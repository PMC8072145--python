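# escprog

Quantitative prognostic modeling for resected esophageal squamous cell
carcinoma (ESCC) from three data modalities: histopathology tissue-microarray
images, CT tumor volumes, and clinical covariates. The package is aimed at
researchers who want a reusable, tested implementation of this class of
multi-modal survival analysis — and at anyone who needs its building blocks:
patch-clustering histology features, from-scratch 3D radiomics, or a fast
L1-penalized Cox estimator with leave-one-out validation.

Because cohorts like this are private, the package ships a synthetic cohort
generator that emulates all three modalities with known ground truth, so the
entire analysis runs, and is tested, end to end from nothing but a seed.

## The method

1. **Pathology — PPCR features.** Each large image is tiled into 50×50
   patches (a 6000×6000 image yields 14,400). Pooled patches are embedded by
   PCA and clustered with k-means into k clusters (default 20). A patient's
   *pathological-patches-cluster-ratio* (PPCR) vector is the fraction of
   their patches in each cluster.
2. **CT — radiomics.** 105 named features over six classes (3D shape,
   first-order, GLCM, GLRLM, GLSZM, GLDM), plus NGTDM as a flagged addendum,
   computed from the volume and ROI mask with IBSI-style definitions
   (sphericity = (36π V²)^⅓ / A, axis lengths 4√λ of the voxel-coordinate
   covariance, texture matrices on a fixed-bin-width discretization, …).
3. **Selection.** Univariate Cox screen at p < 0.2, then recursive feature
   elimination per block down to CT = 8, pathology = 5, clinical = 4
   (17 combined features at reference targets).
4. **Modeling.** LASSO-Cox — the Breslow partial log-likelihood with an L1
   penalty, maximized by coordinate descent with soft-thresholding; the
   penalty chosen by 5-fold cross-validated deviance. The survival score
   SC = x'β ranks risk; patients split at the median SC into low/high-risk
   groups; Harrell's C (apparent and leave-one-out cross-validated),
   Kaplan–Meier overall survival at 1 and 3 years, and the log-rank test
   summarize four nested models: clinical (A), CT+clinical (B),
   pathology+clinical (C), combined (D).

See `docs/methods.md` for every default and numerical convention.

## Worked example

```python
from escprog import SyntheticConfig, make_cohort, compare_models, ModelConfig
from escprog.pipeline import analyze_records

cfg = SyntheticConfig.test_scale(n_patients=40, seed=1)   # 600px images, 32³ CT
records, truth = make_cohort(cfg)                         # 40 synthetic patients
table, ppcr = analyze_records(records, seed=1)            # featurize + select
reports = compare_models(table.features, table.blocks, table.surv,
                         ModelConfig(seed=1))
for name, rep in reports.items():
    print(f"{name:22s} LOOCV C={rep.loocv_c:.3f} log-rank p={rep.logrank_p:.2g}")
```

Output (the hazard in this cohort loads on texture mixing, lesion volume,
TNM stage and CRP):

```
clinical               LOOCV C=0.530 log-rank p=0.033
ct_clinical            LOOCV C=0.705 log-rank p=0.00026
pathology_clinical     LOOCV C=0.743 log-rank p=1.6e-06
combined               LOOCV C=0.741 log-rank p=1.4e-06
```

Each LOOCV C is the concordance of out-of-fold survival scores: 0.5 is
chance, 1.0 perfect risk ranking. The image-derived blocks add ~0.2 of
concordance over clinical covariates alone, and the combined model's median
split separates survival most sharply (log-rank p ≈ 1e-6). The same analysis
is available from the shell:

```bash
escprog run-all --n-patients 20 --seed 1 --k 8 --out run/
```

which writes the cohort, `ppcr.csv`, `ct_features.csv`, `univariate.csv`,
`selection.json`, `reports.json`, `km_curves.csv` and a content-hash manifest
(re-runs skip completed stages). `configs/` ships the test-scale and
full-scale YAML profiles for `escprog run-all --config`.

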
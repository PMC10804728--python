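# dosiofuse

Survival-prognosis modelling for radiotherapy patients from co-registered CT
images and 3D planned-dose distributions ("dosiomics"). The package targets
outcome studies in head-and-neck cancer, where a gross tumor volume (GTV) is
contoured on the planning CT, the dose grid is aligned to the CT lattice via
DICOM geometry, and quantitative image features drive time-to-event models of
overall survival across multiple treatment centers.

## What it does

1. **Ingest** DICOM CT series, RTDOSE grids and RTSTRUCT contours; resample
   the dose onto the CT lattice using header geometry only; rasterize the
   GTV (voxel-center, even-odd rule) and crop to its bounding box.
2. **Fuse** the CT and dose crops by three algorithms:
   *wavelet* — one-level 3D symlet-8 DWT with sub-band averaging (analytically
   the voxelwise mean);
   *WLS* — multi-scale base/detail decomposition (Gaussian + rolling-guidance
   filtering), base layers mixed with visual-saliency weights, detail layers
   merged by a weighted-least-squares solve;
   *LLRR* — slice-wise latent low-rank representation
   `min ‖Z‖* + ‖L‖* + λ‖E‖₁ s.t. X = XZ + LX + E`, fusing low-rank parts by
   weighted average and summing saliency parts.
3. **Extract** 215 IBSI-style features per (volume, GTV) pair — 29 morphology,
   50 first-order, 136 texture (GLCM 25×2 aggregations, GLRLM 16×2, GLSZM 16,
   GLDZM 16, NGTDM 5, NGLDM 17) — on a 1 mm isotropic lattice with 64-level
   fixed-bin-number discretization.
4. **Select** features by five procedures: bootstrap univariate-Cox
   concordance (after a Spearman ρ ≥ 0.9 redundancy prefilter), random-
   survival-forest minimal depth, variable hunting (minimal-depth ordering),
   variable hunting by permutation importance, and Somers' Dxy with
   Gaussian-mutual-information de-duplication. Each returns a top-10 subset.
5. **Model** survival with six estimators behind one `fit`/`predict`-risk
   contract: Cox PH, componentwise likelihood-based boosting (CoxBoost),
   componentwise gradient boosting (glmboost), elastic-net Cox (glmnet),
   random survival forest, and a single survival tree — with grid-search
   tuning by 3-fold cross-validated Harrell C-index.
6. **Evaluate** by leave-one-center-out cross-validation: selection, tuning
   and z-score normalization are learned on the training centers only and
   transferred to the held-out center; performance is the bootstrap
   (1000-resample) distribution of Harrell's C-index, aggregated as
   mean ± SD across the five center folds. Kaplan–Meier median-risk
   stratification with the log-rank test, and Friedman + Nemenyi rank
   comparisons across strategies, complete the benchmark. Seven modelling
   strategies are supported: Clinical (7 covariates), CT, Dose, Dual-CT-Dose
   (215 + 215 + 7 = 437 columns), and the three fusion variants (215 + 7).

A synthetic `phantom` module generates co-registered CT-like/dose-like
volumes with a spherical GTV and multi-center Cox–Weibull survival cohorts
with known coefficients, so the entire pipeline is testable without
clinical data.

## Worked example

```python
import numpy as np
from dosiofuse.phantom import make_phantom_pair, simulate_cohort
from dosiofuse.fusion import FusionConfig, fuse, normalize_for_fusion
from dosiofuse.radiomics import extract_features
from dosiofuse.evaluation import loco_cv

ct, dose, gtv = make_phantom_pair((32, 32, 32), tumor_radius_mm=10.0,
                                  texture_mode="speckle", seed=7)
fused = fuse(normalize_for_fusion(ct, gtv), normalize_for_fusion(dose, gtv),
             FusionConfig(method="llrr"))
feats = extract_features(fused, gtv)
print(len(feats), feats["morph_sphericity"], feats["ih_entropy"])

beta = np.zeros(50); beta[:3] = [1.5, -1.2, 1.0]
co = simulate_cohort([100] * 5, beta, censor_rate=0.3, seed=7,
                     center_shift_sd=0.25)
res = loco_cv(co.features, (co.time, co.event), co.center,
              selector_name="cindex", model_name="coxph",
              n_boot=1000, seed=7)
print(f"{res.grand_mean:.3f} +/- {res.grand_sd:.3f}")
```

This prints `215 0.9900 5.0225` — the fused GTV yields the full 215-feature
vector; the 10 mm phantom sphere has sphericity 0.99 and an intensity-
histogram entropy of 5.02 bits — and `0.860 +/- 0.023`: leave-one-center-out
concordance of a Cox model on bootstrap-C-index-selected features, averaged
over the five held-out centers of a 500-patient synthetic cohort whose
hazard depends on 3 of 50 features. On such a cohort the median-split
Kaplan–Meier stratification of the Cox risk scores separates high- and
low-risk groups at log-rank p ≪ 0.001.

The same steps are available as a CLI:

```bash
dosiofuse simulate --n-per-center 100,100,100,100,100 --out cohort.csv
dosiofuse ingest --ct DIR --dose RTDOSE.dcm --struct RTSTRUCT.dcm --roi GTV --out crops/
dosiofuse fuse --method llrr --ct crops/ct --dose crops/dose --mask crops/gtv --out fused
dosiofuse extract --volume fused --mask crops/gtv --out features.csv
```

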
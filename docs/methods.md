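# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, the parameters that matter, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## Geometry and ingestion

Volumes live on regular lattices described by voxel spacing (mm), an origin
and direction cosines in the DICOM patient (LPS) frame; array axes are
ordered slice/row/column and indices are 0-based. Dose grids are placed on
the CT lattice purely from header geometry (position, orientation, grid
frame offsets) with trilinear interpolation and 0 fill outside the dose
grid's support — physically, no dose was computed there. No image
registration is performed. Contours are rasterized by voxel-center
inclusion (even-odd rule, half-integer-safe); polygons on one slice are
unioned. One named ROI is processed per run; patients with several GTVs
need one run per ROI.

## Fusion

Both inputs are min–max normalized on the GTV crop before fusion; without
this, Hounsfield magnitudes (hundreds) dominate dose magnitudes (tens of
Gy). A constant crop maps to 0.5. Fusion on the crop (rather than the full
volume) is the default; features are mask-restricted either way.

* **Wavelet**: one-level separable 3D DWT, symlet-8, symmetric boundary,
  odd axes padded to even and cropped back. Corresponding sub-bands are
  averaged. Because the transform is linear and *all* eight sub-bands use
  the same rule, the result equals the voxelwise mean to numerical
  precision — asserted as an analytic oracle in the tests.
* **WLS**: each volume is split into a base layer and detail layers by
  iterated rolling-guidance filtering (Gaussian pre-blur σ=2 then 3
  guided-filter iterations, range σ=0.05). Base layers are mixed with
  visual-saliency weights (per-voxel histogram-mass-weighted sum of
  absolute intensity differences, 64 bins). Fused details minimize a data
  term pulled toward the larger-magnitude detail plus a smoothness term
  (λ=0.01, weights inversely tied to local variance of the mean guide)
  whose gradient target is the mean detail field; the target makes
  identical inputs an exact fixed point, so fuse(X, X) = X holds to 1e-6.
  The sparse system is solved directly; an unexpectedly large residual
  raises with the residual reported.
* **LLRR**: latent low-rank representation solved per axial slice by
  inexact augmented-Lagrangian iteration (singular-value thresholding on
  both nuclear terms, soft thresholding on the sparse term; λ=0.8,
  tolerance 1e-6, max 200 iterations, ρ=1.3). The cited formulation is
  two-dimensional, and the axial slice-wise application matches how the
  dose is registered to axial CT; a 3D extension was deliberately not
  invented. Low-rank parts are averaged with weights 0.5/0.5 (the source
  method does not print its weights); saliency parts are summed; the
  sparse noise term is discarded. Consequently fuse(X, X) =
  lowrank(X) + 2·saliency(X) — the documented rule, asserted as such.

## Feature extraction (215 features)

Pipeline: trilinear resample of intensities (nearest for the mask) to
1×1×1 mm, then fixed-bin-number discretization to Ng=64 levels over the
ROI's own range (`level = min(Ng, floor(Ng·(x−min)/(max−min))+1)`; constant
ROI → level 1). Resegmentation/HU-windowing is not applied.

The roster is frozen in `FEATURE_MANIFEST` (29 + 50 + 136 = 215):

* **Morphology (29)**: mesh volume/area from marching cubes on a lightly
  smoothed indicator (σ=0.75; meshing the raw binary field overestimates
  sphere area by ~7% through staircase facets), compactness/sphericity
  family, PCA axis lengths (4√λ), elongation/flatness, volume/area
  densities against the AABB, PCA-oriented bounding box, ellipsoid of
  inertia (Knud Thomsen area approximation), minimum-volume enclosing
  ellipsoid (Khachiyan's algorithm on hull vertices), convex hull,
  centre-of-mass shift, maximum 3D diameter, integrated intensity, and
  Moran's I / Geary's C with inverse-distance weights (subsampled to 1000
  voxels with a fixed seed for larger ROIs).
* **First-order (50)**: 18 intensity statistics (population moments), 23
  intensity-histogram features on the 64 levels (including histogram
  gradients), and 9 intensity–volume-histogram features (V10..V90 at fixed
  intensity fractions, I10/I90, and their differences). The exact IVH
  sub-roster is the package's choice to reach the printed block size of 50
  and is fixed by the manifest.
* **Texture (136)**: GLCM (symmetric, Chebyshev distance 1, 13 unique 3D
  directions; 25 features under both per-direction-averaged and merged
  aggregations), GLRLM (16 × both aggregations), GLSZM (26-connected
  zones), GLDZM (city-block distance to the ROI edge, border voxel = 1,
  array boundary counts as edge), NGTDM (26-neighborhood, coarseness
  capped at 1e6), NGLDM (α=0, distance 1, 17 features). Matrix builders
  are validated against independent brute-force enumerators (pair/run/
  zone/BFS) for exact count equality on random small ROIs.

Features undefined on degenerate ROIs (constant or single-voxel) emit NaN;
selection drops all-NaN columns.

## Synthetic data

`make_phantom_pair` emulates a soft-tissue background (≈0–80 HU) with a
textured spherical tumor (uniform / speckle / gradient) and a smooth dose
peak at the 70 Gy prescription typical of head-and-neck radiotherapy. It
does **not** emulate anatomy, scanner noise spectra, beam geometry or dose
gradients from treatment planning — passing tests demonstrate pipeline
correctness, not clinical feature validity.

`simulate_cohort` draws features i.i.d. standard normal (optionally with
per-center mean shifts, mimicking inter-center distribution shift), event
times from the Cox–Weibull inverse transform
`T = λ(−log U / exp(βᵀx))^{1/k}`, and independent uniform censoring on
(0, c_max) with c_max calibrated by quadrature + bisection so the expected
censored fraction matches the request (within ±5% at n ≥ 500). Center
effects are distribution shifts only; baselines are shared, so
leave-one-center-out tests probe covariate shift, not baseline-hazard
shift. The censoring *indicator* is necessarily correlated with informative
features (high-risk patients die before censoring); independence holds for
the mechanism, which the tests assert on null cohorts and noise features.

A single seed fans out to per-component generators via
`numpy.random.SeedSequence` spawn keys.

## Selection and models

The Spearman prefilter removes, for every pair with |ρ| ≥ 0.9, the member
with the lower orientation-free univariate concordance (the published
description of this rule is internally inconsistent about the direction of
the threshold; the standard redundancy reading is implemented). It is
applied inside the bootstrap-concordance selector only, matching the
procedure's description; a global prefilter remains available by calling
it directly.

Inside bootstrap loops the univariate Cox fits use a vectorized Breslow
scorer (resampling manufactures heavy ties; a per-group Efron loop is two
orders of magnitude slower and changes only the tie handling of a ranking
statistic). Everywhere fitted coefficients are reported — Cox PH and the
likelihood-boosting path — Efron's approximation is used.

Forest-based selectors: minimal depth uses a 250-tree log-rank forest
(node size 15, √p features per split); features a tree never splits on
receive that tree's maximal-depth + 1 as penalty. Variable hunting runs 50
iterations of half/half splits; per iteration a 20-tree forest ranks
candidates (minimal depth, or permutation importance on a 100-row
held-out subsample over the 25 most-split features), and candidates are
forward-added while the test C-index of a 10-tree forest on the growing
set still moves by ≥1% (two consecutive sub-tolerance additions stop the
hunt; an addition joins the tallied set only if it raised the score).
These forest sizes are deliberate problem-size choices for a single-CPU
benchmark: the final ranking is a frequency over 50 iterations (or 250
trees), which is what stabilizes the ordering, not per-iteration forest
depth.

The six models share one contract (higher risk = shorter survival).
CoxBoost is implemented directly: componentwise likelihood boosting where
each step applies the ridge-penalized one-step Newton update
`U_j/(I_j + pen)` to the single covariate maximizing `U_j²/(I_j + pen)`,
with the customary default penalty of 9 × events. glmboost, glmnet, the
random survival forest and the survival tree wrap scikit-survival; Cox PH
wraps lifelines. The coordinate-descent elastic net requires a strictly
positive l1 ratio, so a pure-ridge request (α=0) maps to l1_ratio=1e-6;
at λ→0 this is indistinguishable from the unpenalized fit well inside the
1% equivalence tolerance. Tuning is exhaustive grid search scored by mean
3-fold event-stratified C-index; grids are ordered most-regularized-first
so ties resolve toward regularization; Cox PH is exempt from tuning. The
published hyperparameter grids live in an unavailable supplement, so the
default grids here are package choices, logged with every run.

## Evaluation

Harrell's C counts pairs where the earlier observed time carries an event;
ties in risk count ½. Leave-one-center-out: selection → z-score
normalization learned on training centers (constant columns map to 0) →
tuning → fit → bootstrap evaluation on the held-out center (1000
resamples; replicates without a comparable pair are skipped and counted,
>50% skipped is an error). Two dispersion summaries are emitted: SD across
the five center means (headline convention) and the bootstrap SD within
each fold. The KM cutoff is the median of the evaluated group's risk
scores (high-risk: risk ≥ median); a train-derived cutoff is a one-line
change if wanted. Friedman uses midranks (a fully tied table returns
statistic 0, p=1); Nemenyi pairwise p-values come from the studentized
range distribution with infinite degrees of freedom and are only computed
when Friedman p < 0.05 — the only multiplicity control, by design.

Note one algebraic fact the test suite pins down: the normalization
transfer is idempotent — after one application the training table is
exactly mean-0/SD-1, so a second application is the identity.

## Reference benchmark (study conditions)

Five centers × 100 patients, 50 features of which 3 carry coefficients
(1.5, −1.2, 1.0), Weibull baseline (k=1.2, λ=1000 days), 30% censoring,
center shift SD 0.25. On this cohort the true linear predictor scores
C ≈ 0.85, selector top-10 recovery of ≥2 informative features succeeds in
≥90% of 20 seeds for all five selectors, and the proportional-hazards
models reach LOCO grand-mean C ≈ 0.85. These sizes were chosen once as
realistic desk-scale conditions; the acceptance script re-derives every
number from scratch at run time.

## Known limitations

* The feature roster approximates the reference MATLAB implementation's
  naming and exact sub-roster (its supplement is not public); the manifest
  is the source of truth.
* LLRR fusion is slice-wise 2D; fully-3D low-rank fusion is out of scope.
* No feature harmonization (e.g., batch-effect correction) — distribution
  shift across centers is handled only by normalization transfer.
* Competing risks, time-varying covariates and calibration metrics (Brier,
  time-dependent AUC) are out of scope.
* Variable-hunting null frequencies are draw-dependent: a fixed null cohort
  can contain a spuriously predictive feature that the hunt legitimately
  keeps selecting; the low-frequency property holds in the median across
  cohorts.
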
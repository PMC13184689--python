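# Methods

## Scope and model

`cstlesion` quantifies corticospinal-tract (CST) damage in template space
and links it to per-limb motor outcomes.  The chain is:

1. **Quantitative maps.** MTR is computed voxelwise as
   `(MT0 − MT1)/MT0 × 100` in percent units; voxels with `MT0 ≤ 0` are
   invalid and carry NaN sentinels excluded from every downstream
   statistic.  qT1 maps (ms) are consumed as given — the package does not
   fit T1 from raw acquisitions.
2. **Normative atlas.** Voxelwise healthy-control mean and sample SD
   (n−1 denominator, appropriate for the small HC group).  Voxels whose SD
   falls below a floor — default 0.5 pu for MTR, 50 ms for qT1 — are
   flagged and excluded from z-scoring; without the floor, near-homogeneous
   phantom voxels produce explosive z-values.  The floor is this package's
   regularization choice.
3. **z-score maps.** `z = (map − HC mean)/HC SD` per voxel; the exclusion
   mask is the union of subject-invalid, atlas-invalid and low-SD voxels.
4. **Lesionometry.** Lesion components use 26-connectivity (a voxel's 26
   neighbours), so corner-touching voxels merge.  A component's portion
   (brain, brainstem, cervical C1–C7, thoracic T1–T10) is the majority
   portion of its tract-overlapping voxels; ties go to the more superior
   portion.  A lesion is **severe** when the *mean* z over its
   lesion∩tract, non-excluded voxels passes the signed threshold strictly
   (`mean z < −1.96` for MTR, `> +1.96` for qT1).  The mean was chosen as
   the aggregation because it is robust to single-voxel noise; median or
   any-voxel rules are plausible alternatives and the threshold is a
   parameter.  Components whose lesion∩tract voxels are all excluded are
   flagged unclassifiable rather than silently dropped.
5. **Profiles.** Per-slice records along the inferior–superior axis
   (index 0 = most superior): `% damaged = lesion∩tract voxels / tract
   voxels × 100` and the mean z over the slice's tract voxels.  Slices
   without tract voxels carry no record; per-slice lesion counts sum
   exactly to the lesion∩tract total.
6. **Functional side.** The CST decussates at the brainstem–cord junction:
   a limb maps to the contralateral brain tract plus ipsilateral cord
   tract; upper limbs use the cord only down to C7, lower limbs the full
   cord; whole-CST (both sides, full extent) pooling serves global scores
   such as the EDSS.
7. **Harmonization.** Parametric empirical-Bayes ComBat: features are
   standardized on the covariate model (age, sex, group), per-batch
   location/scale estimates are shrunk under a normal / inverse-gamma
   prior with method-of-moments hyperparameters, iterating the conditional
   posterior modes to a relative tolerance of 1e−4 (max 100 iterations).
   No reference batch; each variable family (MTR ROIs, qT1 ROIs, CMCT,
   anatomical) is harmonized independently.  A single batch yields the
   identity adjustment; constant features are flagged and passed through;
   batches under 3 subjects warn but are shrunk like any other.  The
   implementation reproduces R's `sva::ComBat` to ~1e−14 on identical
   inputs (tested through `Rscript`).
8. **Associations.** Welch t-tests (Satterthwaite df); Cohen's d with
   (n−1)-weighted pooled SD; Pearson chi-square without Yates correction
   by default (a flag enables it); partial Pearson correlations via OLS
   residualization with a t distribution on n − k − 2 df; predictor
   screening retains univariate p < 0.2 strictly; multivariable OLS
   standardizes all variables to unit variance before fitting and reports
   standardized β, adjusted R², per-term p and VIF; logistic models report
   exponentiated coefficients with Wald 95% CIs and the AUC of fitted
   probabilities, with explicit (quasi-)separation errors.  Models are
   complete-case; no imputation.  CMCT abnormality is one-sided
   (`z > 1.96` strictly): only prolongation is pathological, although the
   1.96 value itself is the two-sided P < 0.05 quantile.  Lesion volume
   fractions enter models as `ln(LVF + 0.01)`; the 0.01 offset keeps zero
   fractions finite at ln(0.01) = −4.605 while preserving order.
   Bonferroni thresholds are α/m (0.05/5 = 0.01 for the clinical and
   electrophysiological measures, 0.05/10 = 0.005 for the ROI set).

## The phantom generator

The generator produces the statistical structure the analysis assumes, not
realistic MR images.

**Geometry.** Two parallel tube-shaped tracts (default in-plane radius
`max(1.5, nx/16)` voxels, widening linearly to twice that within the brain
portion to evoke the fanning projection) run through four contiguous
portions covering the inferior–superior axis — brain 41%, brainstem 9%,
cervical 23%, thoracic 27% of the grid — with measurement bands (C4–C6,
T4–T6, T9–T10) placed at the corresponding fractional positions inside
their parent portions.  The reference grid is 48×48×220 at 1 mm; tests and
experiments use a 24×24×110 grid, which preserves every band and the tube
topology at a quarter of the voxel count.

**Healthy controls.** Tract voxels are portion mean + independent Gaussian
voxel noise; defaults are the healthy-control left-CST cohort values
(brain 42.817 ± 0.948 pu, brainstem 46.610 ± 0.826, C4–C6 42.716 ± 1.395,
T4–T6 41.164 ± 2.725, T9–T10 35.541 ± 4.428; cervical outside the band
reuses the band values and mid-thoracic interpolates to 38.35 ± 3.5).  The
rising SD toward the lower cord reproduces the poorer reliability of
thoracic maps.  MT0 is fixed at 100 arbitrary units and
MT1 = MT0·(1 − MTR/100), so `compute_mtr_map` inverts the generator
exactly.  qT1 phantoms are generated directly as maps (brain 850 ± 60 ms
up to T9–T10 920 ± 100 ms) with positive lesion shifts.  What is *not*
emulated: between-subject ROI offsets, spatial autocorrelation, bias
fields, motion, registration error.  Passing tests therefore demonstrate
the correctness of the measurement chain under its own assumptions, not
robustness to real acquisition artifacts.

**Patients.** Ellipsoidal lesions are planted at tract voxels; inside a
lesion the map shifts by `severity_z ×` the local portion SD, so the
expected lesion mean z equals `severity_z`.  Cohort draws: per tract side,
no lesion with probability 0.12, otherwise `1 + Poisson(4.1)` lesions
(≈ 4.5 per affected side); each lesion is severe with probability 0.26
(depth Uniform(−3.5, −2.5)) and mild otherwise (Uniform(−1.5, −0.5));
centre portions follow the cervical-dominant distribution brain 0.30,
brainstem 0.05, cervical 0.40, thoracic 0.25; radii 1.5–3 mm in-plane and
2–5 mm axially.  Overlapping planted lesions merge into single deeper
components, which is why the *classified* severe fraction of a cohort
(~29–32%) sits above the planted 26%.  Ages are N(40, 11) truncated at 18,
sex Bernoulli(0.65 female), disease duration N(8.73, 5.56) truncated at
0.5 years.

**Outcomes.** Per limb,
`CMCT = baseline + 4·(severe cord lesions) + 1.5·(severe brain lesions) +
0.3·(log-LVF above its lesion-free floor) + N(0, 2.5)` ms, with baselines
7.50 ± 1.88 ms (upper) and 14.89 ± 3.07 ms (lower) — the baseline SDs act
as the normative spread for CMCT z-scoring, not as generative noise.  The
effect sizes are free parameters of the generator (no published per-lesion
ms values exist to copy).  They were set so that (a) severity, not sheer
lesion volume, carries the planted association — the hypothesis the cohort
emulates; (b) the conduction-delay effect is cord-dominant for limbs,
matching the structure in which the cord severe-lesion flag is the
explanatory variable for lower-limb conduction; and (c) the severe/normal
CMCT distributions overlap enough that the n = 70 logistic model is
estimable — a flat, larger per-lesion effect produced quasi-complete
separation in a noticeable fraction of cohorts, which no estimable
published model exhibits.  mASIA defaults to 25 minus 3 points per severe
lesion (floor 0, ceiling 15 points lost); EDSS is a coarse function of
total severe burden plus noise.  Site effects are applied to measured ROI
features and CMCT as `x → multiplicative·x + additive` per site, with the
site-free values retained for recovery scoring.

## Numerical conventions and degenerate inputs

- Strict inequalities at every threshold: mean z exactly −1.96 is *not*
  severe; CMCT z exactly 1.96 is *normal*; screening p exactly 0.2 is
  dropped.
- Empty lesion masks yield empty component lists; a lesion covering the
  whole tract makes the extra-lesional mean an error; an empty tract ROI
  makes the volume fraction an error.  The extra-lesional mask excludes
  lesion voxels exactly, with no dilation margin — users wanting a safety
  margin should dilate the lesion mask first.
- Abnormal-area attribution labels a connected abnormal-z area "in lesion"
  from a single overlapping voxel.
- Zero-variance samples, single-class outcomes, perfectly collinear or
  duplicated predictors, rank-deficient ComBat designs and unseen batch
  labels all raise explicit errors rather than returning numbers.
- Logistic separation is detected from Newton/BFGS convergence, coefficient
  magnitude and Wald-SE divergence, and raises `SeparationError`.

## Known limitations

- Empirical-Bayes harmonization leaves residual batch-mean differences on
  the sampling-noise scale σ√(2/n) (it shrinks, it does not force batch
  means equal); exact idempotence likewise holds only in the no-noise
  limit.  Tests check these properties at batch sizes where the noise
  scale sits below the stated bounds.
- The 70 tract sides of a cohort are treated as independent observations
  (two per patient); no mixed-effects correction is applied.
- Registration, lesion segmentation and qT1 map generation are out of
  scope; the package consumes template-space volumes.
- The severity criterion aggregates by the mean z over lesion∩tract; other
  aggregations (median, any-voxel) would call borderline lesions
  differently.
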
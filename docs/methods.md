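# Methods

This note documents the models, conventions and numerical choices behind
`periradiomics`, in the order the pipeline applies them.

## ROI geometry

All morphology is Euclidean in physical millimetres, computed with distance
transforms on the voxel-centre lattice; voxel counts are never used as
distances, so anisotropic grids are handled correctly.  Volumes are
resampled to 1 mm isotropic (linear interpolation for intensities,
nearest-neighbour for masks) before any morphology or texture computation,
which makes the "2 mm / 1 mm" ring construction and the 13 texture
directions well defined.

The peritumoral ring is `{x : d(x, tumor) <= 2 mm}` minus the tumor eroded
by 1 mm, with half-open membership: a tumor voxel strictly deeper than 1 mm
stays intratumoral, a background voxel at exactly 2 mm joins the ring.  On a
1 mm grid this yields an exactly 3 mm radial extent along any coordinate
axis through a spherical mask.  Two consequences of the voxel-centre metric
are worth knowing: (i) the construction is bit-reproducible and matches an
exhaustive pairwise-distance oracle exactly; (ii) the ring *volume* runs
~10-15% below the continuum shell `(4/3)pi[(r+2)^3 - (r-1)^3]` at 1 mm
spacing because centre-to-centre distances overestimate the distance to the
region boundary by up to half a voxel on each surface; the gap closes as
the grid refines (about 9% at 0.5 mm).

The intratumoral ROI paired with the ring is the eroded tumor, so the two
ROIs are disjoint by construction.  Ring voxels outside a configurable HU
retention window (default [-100, 300]) are removed, which strips air
cavities and contrast-filled vessels; adjacent organs can be removed with an
explicit exclusion mask, since no intensity rule can identify them reliably.

## Feature catalog

Each ROI yields exactly 292 features: 14 first-order intensity statistics
and 8 mesh-based shape descriptors on the original image, plus 45 texture
features (22 GLCM, 13 GLRLM, 5 GLSZM, 5 NGTDM) on each of 6 image variants
— the original image, the one-level 3D wavelet approximation sub-band
(`coif1`, detail bands zeroed, reconstructed on the original grid), and
Laplacian-of-Gaussian responses at sigma = 1.0, 1.5, 2.0, 2.5 mm.  Two ROIs
give 584 features per patient.  The catalog is frozen in a versioned
manifest whose constructor asserts the 14/8/270 arithmetic.

Numerical conventions:

* Texture operates on 32 equal-width bins over the in-ROI intensity range,
  so all texture features are invariant to global HU shifts; a constant ROI
  maps to level 1.
* GLCM and GLRLM use offset distance 1 voxel over the 13 unique directions
  of the 26-neighbourhood, symmetrized (GLCM) and averaged across
  directions at the feature level; directions without voxel pairs are
  skipped, and an ROI with no co-occurring pair in any direction raises a
  degenerate-texture error naming the family.
* GLSZM zones use 26-connectivity; NGTDM uses the 26-neighbourhood mean
  gray-tone difference, with the coarseness denominator of a perfectly flat
  ROI mapped to the documented sentinel 1e6 (finite, deterministic, no
  NaN).
* First-order variance/SD are population moments; skewness and kurtosis
  (Pearson, non-excess) are defined as 0 for a constant ROI; entropy and
  uniformity use the same 32-bin histogram as the texture discretization.
* Surface area comes from a marching-cubes mesh of the mask indicator
  lightly smoothed with a 0.8-voxel Gaussian; meshing the raw binary field
  overestimates a sphere's area by ~9% through lattice faceting, and the
  smoothed level set removes almost all of that bias (digital-sphere
  sphericity 0.995 instead of 0.92).  Masks too thin to survive smoothing
  fall back to the raw indicator; a single voxel falls back to its cube.
* The LoG kernel is assembled from analytically sampled 1D Gaussian
  derivatives (truncated at 4.5 sigma) as the sum of three separable terms;
  the second-derivative kernel is re-centred to zero sum so constant input
  maps exactly to zero.  Sigma is interpreted in millimetres and converted
  per axis by the voxel spacing.

## Radiomics signature (RS)

The two-class target is relapse within 60 months: label 1 if an event
occurred at or before 60 months, 0 if follow-up passed 60 months
event-free.  Patients censored before 60 months carry no usable training
label; they are excluded from classifier *training* only and remain in all
survival analyses and scoring.

Features are z-scored with training-cohort constants (zero-variance columns
dropped with a warning); validation data are always transformed with the
stored training constants.  SVM-RFE ranks features by squared weight of a
repeatedly refit linear soft-margin SVM, eliminating the worst
`ceil(10% of remaining)` (at least 1) per iteration.  The retained subset
size and the SVM cost C (grid 0.01, 0.1, 1, 10, 100) are chosen by
maximizing stratified cross-validated AUC over the elimination path, with
two safeguards that matter on small cohorts:

* the CV is *nested* — each fold computes its own RFE ranking from its
  training rows only.  A single ranking computed on all rows leaks the
  held-out labels into the subset-size choice and inflates the inner AUC
  dramatically (we observed 0.95 inner vs 0.50 external before nesting);
* the fold split is repeated 3 times to damp the winner's-curse variance of
  the (size, C) search.

The SVM uses class-balanced error weights: the hyperplane *side* defines
the risk groups, and with unbalanced relapse prevalence an unweighted fit
parks the boundary at the class prior rather than between the classes.
Ties in the CV objective prefer the smaller subset, then the smaller C.

The RS score is `orientation x (w.z + b)`.  The orientation sign is fixed
on the training cohort so that the side of the hyperplane with the smaller
relapse fraction scores *high* (high RS = good prognosis); a score of
exactly 0 is assigned to the low group.  Both the continuous score and the
binary group are exposed, since the high/low split drives the survival
analyses while the score drives ROC evaluation.  Reported AUCs use the
relapse-risk direction (−score).  The signature size is a data-dependent
outcome of the CV, never a fixed constant.

## Survival statistics

Kaplan-Meier (with Greenwood variance), the k-sample log-rank test and Cox
proportional-hazards fits (Efron tie correction — months-resolution data
are heavily tied — Newton-Raphson on the partial likelihood) are delegated
to lifelines behind this package's interfaces.  Inference conventions:
Wald p-values and `exp(beta +/- 1.96 SE)` confidence intervals, matching
HR (95% CI) reporting; all tests two-sided at alpha = 0.05.  A monotone
likelihood or non-convergence is surfaced as a flagged fit; the pipeline's
only automatic remedy is an explicit, logged refit with a small ridge
penalty (0.1), which is the standard stabilization for a separated binary
covariate.

Cohort comparisons use Pearson chi-square *without* continuity correction
— verified to reproduce the published cohort-balance p-values from their
printed contingency tables to three decimals — with Fisher's exact test as
the fallback for 2x2 tables containing an expected count below 5, and
Welch's t-test for continuous variables.  The univariate screen fits one
Cox model per candidate covariate (binary factors coded 0/1, T/N stage
ordinal 1..5, age and tumor size dichotomized at 60 years / 4 cm) and
retains Wald p < 0.05.

## Prognostic models and evaluation

The nomogram maps a fitted Cox model to the conventional 0-100 point scale
(the variable with the largest |beta| x range spans exactly 100 points) and
predicts survival through the full Breslow baseline curve evaluated at the
training covariate means, so nomogram predictions are numerically identical
to direct Cox predictions on the fitted step grid.  Calibration bins
patients into predicted-survival quartiles and compares with the KM
estimate per bin, with seeded percentile-bootstrap CIs (B = 200).

Model comparison quantities are definition-dependent, so the definitions
are fixed here:

* **Brier / IBS / PEC** — IPCW-weighted squared error of predicted S(t|x),
  censoring distribution estimated by KM on the censoring indicator;
  subjects censored by t contribute nothing, weights with G = 0 are dropped
  with a logged count.  IBS is the trapezoidal integral of the PEC over
  [0, 60] months divided by 60.
* **NRI** — category-free (continuous) at the 60-month horizon with IPCW
  status weights; this makes NRI(new, old) = −NRI(old, new) exact.
  Bootstrap CI (B = 1000, seeded).
* **Decision curves** — survival-adapted net benefit
  `TP/n − (FP/n) p_t/(1−p_t)` at the 5-year horizon over thresholds
  0.05..0.95 (step 0.05), with the event fraction inside the
  predicted-positive group estimated by KM; an empty positive set scores 0.
  Treat-all and treat-none references included.
* The comparator model throughout (C-index, IBS, NRI, DCA) is a Cox fit on
  TNM stage alone.

The chemotherapy-benefit analysis reports, within each stage stratum (II,
III, II+III), the chemo-vs-no-chemo HR per RS group and the Wald p of the
chemotherapy x RS-group product term in a joint Cox model.

## Synthetic cohort

The generator produces the statistical structure the analysis assumes, not
realistic anatomy.  Each phantom is an ellipsoidal tumor (kept >= 3 voxels
inside a >= 32^3 grid so the 2 mm dilation stays in-grid) on a 50 HU
soft-tissue plateau, with Gaussian noise smoothed by a 2 mm kernel (the
simplest field with tunable spatial correlation reachable by GLCM-class
features).  The noise SD inside the tumor and a 3 mm shell depends on a
latent risk class — 10 HU (indolent) vs 20 HU (aggressive) — multiplied by
a per-patient lognormal factor (sigma = 0.3) so the classes overlap the way
biological heterogeneity does and texture is an informative but imperfect
class surrogate; a deterministic mapping would let the classifier
interpolate its training labels and degenerate the downstream Cox fits.
Optional -900 HU air pockets and +400 HU vessel rods support exclusion
tests.

DFS follows a proportional-hazards model,
`h = h0 exp(beta_class A + beta_stage S + beta_chemo X + beta_int X A)`,
with defaults beta_class = log 4 (aggressive vs indolent), beta_stage =
log 2, beta_chemo = 0 and beta_int = log 0.4: chemotherapy benefits only
the aggressive class, the pattern the treatment-interaction analysis is
built to detect.  The baseline hazard h0 = 0.004/month is calibrated to the
reported 5-year DFS magnitudes of the two risk groups (~0.8 vs ~0.25 once
class, stage and chemotherapy mix in).  Censoring is uniform on (0, 96]
months (administrative follow-up), independent of everything else.
Covariate frequencies are coupled to the latent class (aggressive enriched
for stage III, elevated CA19-9, deeper T and higher N) so the univariate
screen has signal.  One integer seed drives everything; identical seeds
give bit-identical phantoms and tables.

What passing on this generator does **not** show: robustness to scanner or
reconstruction effects, segmentation variability, non-proportional
hazards, informative censoring, or texture structure richer than a single
latent amplitude factor — on real CT the signature would draw on many more
independent features than the parsimonious subsets selected here.

## Problem sizes and determinism

The test suite exercises the full pipeline at the default study size of
300 training + 300 validation patients on 32^3 phantoms (about 3 minutes
end to end on one CPU); the treatment-interaction power check uses 20
replicates of n = 600 at the clinical-simulation level; null-calibration
checks use 40-100 replicates at n = 120-500.  All stochastic stages (fold
splits, bootstraps, simulations) consume explicit integer seeds recorded in
the run manifest, and the pipeline's training/validation split is an
explicit cohort label, never random.

## Known limitations

* The 270-texture composition (45 features x 6 variants) is one concrete
  catalog consistent with the printed counts; other splits across families
  and variants would satisfy the same totals.
* Fisher's exact fallback applies only to 2x2 tables; larger sparse tables
  retain chi-square with a logged warning.
* The univariate screen codes each covariate as a single column; multi-level
  factors are tested ordinally rather than via multi-df likelihood-ratio
  tests.
* NRI and DCA values depend on the stated variant choices and are not
  comparable across definitions.
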
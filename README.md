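# periradiomics

Combined intratumoral + peritumoral CT radiomics for disease-free-survival
modelling in locally advanced (stage II/III) gastric cancer — a tested,
reusable implementation of the full analysis stack: peritumoral ring
construction, a 584-feature texture catalog, an SVM-RFE risk signature, and
the survival / nomogram / chemotherapy-benefit evaluation machinery, all
exercisable end-to-end on synthetic CT phantoms so no patient data are
required.

## Who this is for

Researchers who want to apply or audit the *method* — ring-based
peritumoral radiomics with an SVM-derived prognostic score — on their own
segmented CT data, or to study its statistical behaviour under controlled
simulated conditions.

## The model

**ROIs.** From a binary tumor mask on a 1 mm-isotropic CT grid, two regions
are built with mm-true Euclidean distance transforms: the tumor eroded by
1 mm (intratumoral), and a ring `{x : d(x, tumor) <= 2 mm} \ (tumor
eroded by 1 mm)` — a 3 mm invasive-margin shell (2 mm outside + 1 mm inside
the contour).  Air, vessels (HU window) and optional organ masks are
excluded from the ring.

**Features.** Per ROI, 292 features: 14 first-order + 8 shape + 45 texture
features (22 GLCM, 13 GLRLM, 5 GLSZM, 5 NGTDM) on each of 6 image variants
(original, wavelet approximation, LoG at sigma = 1.0/1.5/2.0/2.5 mm); 584
per patient over both ROIs.

**Signature.** With two classes y ∈ {relapse within 5 years, not}, a linear
soft-margin SVM `d(x) = w·z + b` is trained on z-scored features; SVM-RFE
iteratively removes the 10% of features with the smallest `w_j^2`; subset
size and cost C are chosen by repeated nested cross-validated AUC.  The
radiomics score is `RS(x) = s·d(x)` with the sign s fixed so that high RS
lies on the hyperplane side with fewer relapses; `RS > 0` defines the
high (good-prognosis) group.

**Evaluation.** Kaplan-Meier / log-rank between RS groups; univariate Cox
screen (p < 0.05) feeding a multivariate Cox model (Efron ties, Wald
inference); a 0-100-point nomogram with Breslow baseline; Harrell's C,
IPCW Brier / integrated Brier score / prediction-error curves, continuous
NRI and decision-curve net benefit against a stage-only comparator; and a
chemotherapy x RS interaction analysis with per-stratum treatment hazard
ratios.

See `docs/methods.md` for every numerical convention and the synthetic
cohort's generative model.

## Worked example

Run the whole study on a simulated cohort (200 training + 200 validation
patients, 32^3 phantoms; ~3 minutes):

```bash
periradiomics run-all --out run/ --seed 20240101
```

The run prints the metrics bundle; with this seed it contains (abridged):

```json
"radiomics_signature": {
  "n_selected_features": 2,
  "validation": {"logrank_p": 0.0097, "auc_5yr": 0.616, "n_high": 108, "n_low": 92}
},
"model_comparison": {
  "validation": {"c_index_nomogram": 0.624, "c_index_stage": 0.576,
                 "nri_vs_stage": 0.119, "ibs_nomogram": 0.166}
}
```

and `run/chemo_benefit.csv` holds the treatment-interaction table, which
recovers the planted effect pattern (chemotherapy was simulated to benefit
only the aggressive latent class, which the signature maps to low RS):

| stage  | RS group | chemo vs no chemo HR (95% CI) | interaction p |
|--------|----------|-------------------------------|---------------|
| II+III | high     | 1.26 (0.74-2.13)              | 0.0014        |
| II+III | low      | 0.40 (0.25-0.64)              | 0.0014        |

Read: patients scored low-RS relapse sooner, and only they benefit from
chemotherapy — high-RS patients show no detectable effect.  The signature
selected 2 texture features; on these phantoms tumor heterogeneity is a
single latent amplitude factor, so a parsimonious subset is the correct
recovery (real CT texture is richer and supports larger signatures).

Other artifacts written: per-cohort 584-column feature matrices, the
serialized signature (`rs_model.json`: features, weights, bias,
orientation, standardization constants, seeds), univariate screen and
multivariate Cox tables, calibration / prediction-error / decision-curve
data as tidy CSV, and a run manifest with stage timings and output digests.

The library surface mirrors the CLI: `synthetic.generate_cohort`,
`roi.build_peritumoral_ring`, `features.extract_patient_features`,
`signature.select_signature` / `rs_score`, `survival.cox_fit` /
`logrank_test`, `prognostic.build_nomogram` / `decision_curve` /
`chemo_benefit_analysis`, `pipeline.run_pipeline`.

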
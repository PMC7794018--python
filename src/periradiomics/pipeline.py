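"""End-to-end pipeline: simulate -> ROI -> extract -> signature -> survival
-> prognostic evaluation -> report bundle.

The training cohort is used for every fitted quantity (standardization,
RFE ranking, C, subset size, orientation, Cox coefficients, nomogram,
baseline survival); the validation cohort is only scored and evaluated.
Cohort membership is an explicit label, never a random split.  Every stage
logs its parameters and output digests into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .datatypes import DegenerateROIError
from .features import FeatureManifest, extract_patient_features
from .prognostic import (
    brier,
    build_nomogram,
    calibration_curve,
    chemo_benefit_analysis,
    decision_curve,
    integrated_brier,
    nri,
)
from .roi import apply_exclusions, build_peritumoral_ring, erode_tumor, resample_isotropic
from .signature import (
    SignatureConfig,
    assign_groups,
    make_labels,
    roc_auc,
    rs_score,
    select_signature,
)
from .survival import (
    cox_fit,
    encode_clinical,
    harrell_c,
    km_estimate,
    logrank_test,
    univariate_screen,
)
from .synthetic import SimulationConfig, generate_phantom, records_to_frame, simulate_clinical

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class RingParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outer_mm: float = Field(2.0, ge=0)
    inner_mm: float = Field(1.0, ge=0)
    hu_low: float = -100.0
    hu_high: float = 300.0
    target_spacing_mm: float = Field(1.0, gt=0)


class SimulationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_train: int = Field(200, ge=4)
    n_validation: int = Field(200, ge=4)
    beta_class: float = float(np.log(4.0))
    beta_stage: float = float(np.log(2.0))
    beta_chemo: float = 0.0
    beta_interaction: float = float(np.log(0.4))
    baseline_hazard: float = Field(0.004, gt=0)
    censor_window: float = Field(96.0, gt=0)
    texture_contrast: tuple[float, float] = (10.0, 20.0)
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


class SignatureParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    horizon_months: float = Field(60.0, gt=0)
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_folds: int = Field(5, ge=2)
    max_subset_candidates: int = Field(16, ge=2)


class PipelineConfig(BaseModel):
    """Schema-validated configuration of a full run."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str
    seed: int = Field(20240101, ge=0, lt=2**31)
    simulation: SimulationParams = SimulationParams()
    ring: RingParams = RingParams()
    signature: SignatureParams = SignatureParams()
    horizons: tuple[float, ...] = (12.0, 36.0, 60.0)
    ibs_tau: float = Field(60.0, gt=0)


def validate_config(path) -> PipelineConfig:
    """Load + schema-check a JSON config; unknown keys are rejected with a
    field-level message."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"invalid pipeline config: {details}") from exc


def _sha256_of(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    elif isinstance(obj, (bytes, bytearray)):
        payload = bytes(obj)
    else:
        payload = str(obj).encode()
    return hashlib.sha256(payload).hexdigest()


def _simulate_cohort(params: SimulationParams, n: int, seed: int) -> tuple[pd.DataFrame, SimulationConfig]:
    cfg = SimulationConfig(
        n_patients=n,
        beta_class=params.beta_class,
        beta_stage=params.beta_stage,
        beta_chemo=params.beta_chemo,
        beta_interaction=params.beta_interaction,
        baseline_hazard=params.baseline_hazard,
        censor_window=params.censor_window,
        texture_contrast=params.texture_contrast,
        volume_shape=params.volume_shape,
        spacing=params.spacing,
        rng_seed=seed,
    )
    return records_to_frame(simulate_clinical(cfg)), cfg


def extract_cohort_features(
    clinical: pd.DataFrame, sim_cfg: SimulationConfig, ring_params: RingParams,
    manifest: FeatureManifest,
) -> pd.DataFrame:
    """Phantom -> ROIs -> 584 features for every patient of one cohort."""
    rows = {}
    for i, rec in clinical.reset_index(drop=True).iterrows():
        volume, tumor_mask = generate_phantom(sim_cfg, rec["latent_class"], i)
        volume, tumor_mask = resample_isotropic(volume, tumor_mask, ring_params.target_spacing_mm)
        try:
            tumor = erode_tumor(tumor_mask, ring_params.inner_mm)
            ring = build_peritumoral_ring(tumor_mask, ring_params.outer_mm, ring_params.inner_mm)
            ring = apply_exclusions(ring, volume, ring_params.hu_low, ring_params.hu_high)
            rows[rec["patient_id"]] = extract_patient_features(volume, tumor, ring, manifest)
        except DegenerateROIError as exc:
            logger.error("patient %s skipped: %s", rec["patient_id"], exc)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=manifest.ids)
    matrix.index.name = "patient_id"
    return matrix


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study pipeline on synthetic cohorts; returns the
    metrics dictionary and writes the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = FeatureManifest()
    stages: list[dict] = []
    rng_master = np.random.SeedSequence(config.seed)
    seed_train, seed_val = (int(s.generate_state(1)[0] % (2**31)) for s in rng_master.spawn(2))

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        result = fn()
        stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        logger.info("stage %-12s done in %.1fs", name, time.perf_counter() - t0)
        return result

    # -- simulate ---------------------------------------------------------
    clin_train, cfg_train = _simulate_cohort(config.simulation, config.simulation.n_train, seed_train)
    clin_val, cfg_val = _simulate_cohort(config.simulation, config.simulation.n_validation, seed_val)
    clin_train.insert(0, "cohort", "training")
    clin_val.insert(0, "cohort", "validation")
    clin_train["patient_id"] = "TR-" + clin_train["patient_id"]
    clin_val["patient_id"] = "VA-" + clin_val["patient_id"]
    clinical = pd.concat([clin_train, clin_val], ignore_index=True)
    clinical.drop(columns="latent_class").to_csv(out / "clinical.csv", index=False)

    # -- features ---------------------------------------------------------
    feats_train = _stage("extract-train", lambda: extract_cohort_features(
        clin_train.assign(patient_id=clin_train["patient_id"]), cfg_train, config.ring, manifest))
    feats_val = _stage("extract-val", lambda: extract_cohort_features(
        clin_val, cfg_val, config.ring, manifest))
    feats_train.to_csv(out / "features_training.csv")
    feats_val.to_csv(out / "features_validation.csv")
    clin_train = clin_train.set_index("patient_id").loc[feats_train.index].reset_index()
    clin_val = clin_val.set_index("patient_id").loc[feats_val.index].reset_index()

    # -- signature (training only) ---------------------------------------
    labels = make_labels(clin_train["dfs_months"], clin_train["event"],
                         config.signature.horizon_months)
    sig_cfg = SignatureConfig(
        horizon_months=config.signature.horizon_months,
        c_grid=config.signature.c_grid,
        n_folds=config.signature.n_folds,
        max_subset_candidates=config.signature.max_subset_candidates,
        seed=config.seed,
    )
    model = _stage("train-rs", lambda: select_signature(feats_train, labels, sig_cfg))
    model.to_json(out / "rs_model.json")

    scores_train = rs_score(model, feats_train)
    scores_val = rs_score(model, feats_val)
    groups_train = assign_groups(scores_train)
    groups_val = assign_groups(scores_val)

    # -- survival analyses ------------------------------------------------
    def _survival_block():
        block = {}
        for name, clin, scores, groups in (
            ("training", clin_train, scores_train, groups_train),
            ("validation", clin_val, scores_val, groups_val),
        ):
            chi2, df, p = logrank_test(clin["dfs_months"], clin["event"], groups)
            lab = make_labels(clin["dfs_months"], clin["event"], config.signature.horizon_months)
            auc = sens = spec = float("nan")
            if lab.usable.sum() and len(np.unique(lab.labels[lab.usable])) == 2:
                # -score is the relapse-risk direction (high RS = good prognosis)
                auc, sens, spec = roc_auc(-scores[lab.usable], lab.labels[lab.usable])
            block[name] = {"logrank_chi2": chi2, "logrank_p": p,
                           "auc_5yr": auc, "sensitivity": sens, "specificity": spec,
                           "n_high": int((groups == "high").sum()),
                           "n_low": int((groups == "low").sum())}
        return block
    rs_block = _stage("survival", _survival_block)

    # univariate screen on training, multivariate Cox with RS + survivors
    enc_train = encode_clinical(clin_train)
    enc_val = encode_clinical(clin_val)
    enc_train["rs_high"] = (groups_train == "high").astype(int)
    enc_val["rs_high"] = (groups_val == "high").astype(int)
    candidates = [c for c in enc_train.columns if c != "rs_high" and enc_train[c].nunique() > 1]
    selected, screen_table = univariate_screen(
        enc_train, clin_train["dfs_months"], clin_train["event"], candidates)
    screen_table.to_csv(out / "univariate_screen.csv", index=False)

    multivar_cols = ["rs_high"] + selected
    fit_train = cox_fit(enc_train[multivar_cols], clin_train["dfs_months"], clin_train["event"])
    if not fit_train.converged:
        logger.warning("training multivariate Cox flagged (separation/collinearity); "
                       "refitting with ridge penalizer 0.1")
        fit_train = cox_fit(enc_train[multivar_cols], clin_train["dfs_months"],
                            clin_train["event"], penalizer=0.1)
        fit_train.converged = True  # explicit, logged fallback
    fit_train.summary_frame().to_csv(out / "multivariate_cox_training.csv")
    try:
        fit_val = cox_fit(enc_val[multivar_cols], clin_val["dfs_months"], clin_val["event"])
        fit_val.summary_frame().to_csv(out / "multivariate_cox_validation.csv")
    except (ValueError, RuntimeError) as exc:
        logger.warning("validation multivariate Cox not estimable: %s", exc)

    # -- nomogram + model comparison --------------------------------------
    def _evaluate():
        horizons = tuple(sorted(set(config.horizons) | {float(config.signature.horizon_months)}))
        nomo = build_nomogram(fit_train, enc_train[multivar_cols], horizons)
        stage_fit = cox_fit(enc_train[["stage"]], clin_train["dfs_months"], clin_train["event"])
        stage_nomo = build_nomogram(stage_fit, enc_train[["stage"]], horizons)
        metrics = {}
        for name, enc, clin in (("training", enc_train, clin_train),
                                ("validation", enc_val, clin_val)):
            t, e = clin["dfs_months"].to_numpy(), clin["event"].to_numpy()
            h60 = float(config.signature.horizon_months)
            risk_nomo = 1.0 - nomo.predict_survival(enc, h60)
            risk_stage = 1.0 - stage_nomo.predict_survival(enc, h60)
            pred_nomo = lambda tt: nomo.predict_survival(enc, float(tt))
            pred_stage = lambda tt: stage_nomo.predict_survival(enc, float(tt))
            nri_est, nri_ci = nri(risk_nomo, risk_stage, t, e, h60, seed=config.seed)
            grid = np.linspace(1.0, config.ibs_tau, 20)
            pec = pd.DataFrame({
                "time": grid,
                "nomogram": [brier(pred_nomo(g), t, e, g) for g in grid],
                "stage": [brier(pred_stage(g), t, e, g) for g in grid],
            })
            pec.to_csv(out / f"prediction_error_{name}.csv", index=False)
            cal = calibration_curve(nomo.predict_survival(enc, h60), t, e, h60,
                                    seed=config.seed)
            cal.to_csv(out / f"calibration_{name}_{int(h60)}m.csv", index=False)
            dca = decision_curve({"nomogram": risk_nomo, "stage": risk_stage}, t, e, h60)
            dca.net_benefit.to_csv(out / f"decision_curve_{name}.csv")
            metrics[name] = {
                "c_index_nomogram": harrell_c(nomo.linear_predictor(enc), t, e),
                "c_index_stage": harrell_c(enc["stage"].to_numpy(), t, e),
                "ibs_nomogram": integrated_brier(pred_nomo, t, e, config.ibs_tau),
                "ibs_stage": integrated_brier(pred_stage, t, e, config.ibs_tau),
                "nri_vs_stage": nri_est, "nri_ci": list(nri_ci),
            }
        return metrics
    eval_metrics = _stage("evaluate", _evaluate)

    # -- chemotherapy benefit ---------------------------------------------
    combined = pd.concat([clin_train, clin_val], ignore_index=True)
    groups_all = np.concatenate([groups_train, groups_val])
    chemo_table = _stage("chemo-benefit",
                         lambda: chemo_benefit_analysis(combined, groups_all))
    chemo_table.to_csv(out / "chemo_benefit.csv", index=False)

    metrics = {
        "radiomics_signature": {
            "n_selected_features": len(model.selected_feature_ids),
            "C": model.C, "cv_auc": model.cv_auc,
            **rs_block,
        },
        "model_comparison": eval_metrics,
        "univariate_selected": selected,
        "seeds": {"master": config.seed, "train": seed_train, "validation": seed_val},
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    run_manifest = {
        "config": json.loads(config.model_dump_json()),
        "stages": stages,
        "digests": {
            "features_training": _sha256_of(feats_train),
            "features_validation": _sha256_of(feats_val),
            "rs_model": _sha256_of(model.to_json()),
            "metrics": _sha256_of((out / "metrics.json").read_bytes()),
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return metrics
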
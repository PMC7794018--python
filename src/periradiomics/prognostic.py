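"""Prognostic model evaluation: nomogram, calibration, Brier/IBS/PEC,
continuous NRI, decision curves, and the chemotherapy-benefit analysis.

Conventions fixed here (they matter because several of these quantities are
definition-dependent):

* Nomogram points follow the rms convention — the variable with the largest
  |beta| x range spans exactly 100 points; predictions use the Breslow
  baseline survival, so nomogram output is numerically identical to direct
  Cox predictions.
* The Brier score is IPCW-weighted with the censoring distribution estimated
  by Kaplan-Meier on the censoring indicator; the IBS is the trapezoidal
  integral of the prediction-error curve over [0, tau] divided by tau.
* The NRI is the category-free (continuous) variant at a fixed horizon with
  IPCW handling of censoring, so NRI(new, old) = -NRI(old, new) exactly.
* Decision-curve net benefit at threshold p_t is
  TP/n - (FP/n) * p_t / (1 - p_t), with event status at the horizon
  estimated by Kaplan-Meier inside the predicted-positive group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import CoxFit, cox_fit, interaction_cox, km_estimate

__all__ = [
    "Nomogram",
    "build_nomogram",
    "calibration_curve",
    "brier",
    "integrated_brier",
    "prediction_error_curve",
    "nri",
    "decision_curve",
    "chemo_benefit_analysis",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (12.0, 36.0, 60.0)


# --------------------------------------------------------------------------
# nomogram

@dataclass
class Nomogram:
    """Point mappings of a Cox model on the conventional 0-100 scale.

    Holds the full Breslow baseline survival curve (step function, evaluated
    at the training covariate means) so survival can be predicted at any
    time, plus the anchor horizons printed on the nomogram itself.
    """

    variables: list[str]
    coefficients: np.ndarray
    reference: np.ndarray        # covariate value mapped to 0 points, per variable
    scale: float                 # points per unit of linear predictor
    lp_center: float             # linear predictor at the training covariate means
    baseline_times: np.ndarray
    baseline_values: np.ndarray
    horizons: tuple[float, ...]

    @property
    def baseline_survival(self) -> dict[float, float]:
        """S0 at the anchor horizons."""
        return {h: self._s0(h) for h in self.horizons}

    def _s0(self, t: float) -> float:
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.baseline_values[idx])

    def points(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-variable and total points for each row of X."""
        pts = {}
        for k, var in enumerate(self.variables):
            pts[var] = self.coefficients[k] * (X[var].to_numpy() - self.reference[k]) * self.scale
        df = pd.DataFrame(pts, index=X.index)
        df["total_points"] = df.sum(axis=1)
        return df

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.variables].to_numpy() @ self.coefficients

    def predict_survival(self, X: pd.DataFrame, t: float) -> np.ndarray:
        return self._s0(t) ** np.exp(self.linear_predictor(X) - self.lp_center)


def build_nomogram(
    fit: CoxFit, data: pd.DataFrame, horizons=DEFAULT_HORIZONS
) -> Nomogram:
    """Build the point mapping of a converged Cox fit on ``data`` (the
    training covariates, used for per-variable ranges and the Breslow
    baseline)."""
    if not fit.converged:
        raise ValueError("nomogram requires a converged Cox fit")
    beta = fit.coefficients
    X = data[fit.variables]
    lo = X.min(axis=0).to_numpy()
    hi = X.max(axis=0).to_numpy()
    ranges = np.abs(beta) * (hi - lo)
    if np.max(ranges) <= 0:
        raise ValueError("degenerate covariate ranges: no variable spans any points")
    scale = 100.0 / np.max(ranges)
    # reference level = end of the range with the smaller beta*x (0 points)
    reference = np.where(beta >= 0, lo, hi)
    baseline = fit.fitter.baseline_survival_["baseline survival"]
    lp_center = float(X.mean(axis=0).to_numpy() @ beta)
    return Nomogram(
        variables=list(fit.variables),
        coefficients=beta.copy(),
        reference=reference,
        scale=scale,
        lp_center=lp_center,
        baseline_times=baseline.index.to_numpy(dtype=float),
        baseline_values=baseline.to_numpy(dtype=float),
        horizons=tuple(float(h) for h in horizons),
    )


# --------------------------------------------------------------------------
# calibration

def calibration_curve(
    predicted_survival, times, events, horizon: float,
    n_groups: int = 4, bootstrap: int = 200, seed: int = 0,
) -> pd.DataFrame:
    """Observed (KM) vs mean predicted survival at ``horizon`` within
    quantile bins of the prediction, with percentile bootstrap CIs on the
    observed estimate.  Bins that collapse (ties in the predictions) are
    merged and logged."""
    pred = np.asarray(predicted_survival, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_groups + 1)))
    if len(edges) - 1 < n_groups:
        logger.info("calibration: tied predictions collapsed %d bins to %d",
                    n_groups, len(edges) - 1)
    if len(edges) < 2:  # constant predictions: a single usable bin
        edges = np.array([pred.min() - 1e-12, pred.max() + 1e-12])
    bins = np.clip(np.searchsorted(edges, pred, side="right") - 1, 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(len(edges) - 1):
        sel = bins == b
        if not sel.any():
            continue
        observed = km_estimate(times[sel], events[sel]).survival_at(horizon)
        idx = np.flatnonzero(sel)
        boot = []
        for _ in range(bootstrap):
            take = rng.choice(idx, size=len(idx), replace=True)
            if events[take].sum() == 0 and (times[take] <= horizon).all():
                continue
            boot.append(km_estimate(times[take], events[take]).survival_at(horizon))
        lo, hi = (np.percentile(boot, [2.5, 97.5]) if boot else (np.nan, np.nan))
        rows.append({
            "bin": b, "n": int(sel.sum()),
            "predicted": float(pred[sel].mean()),
            "observed": float(observed),
            "observed_ci_lower": float(lo), "observed_ci_upper": float(hi),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Brier / IBS / PEC

def _censoring_km(times, events) -> "km_estimate":
    return km_estimate(times, 1 - np.asarray(events, dtype=int))


def brier(predicted_survival, times, events, t: float) -> float:
    """IPCW Brier score of predicted S(t|x) at time t.

    Subjects with an event by t contribute (0 - S)^2 weighted by 1/G(T-);
    subjects still at risk past t contribute (1 - S)^2 weighted by 1/G(t);
    subjects censored by t contribute 0.  Terms with censoring weight 0 are
    dropped with a logged count.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    G = _censoring_km(times, events)
    g_at_t = G.survival_at(t)
    eps = 1e-12
    contrib = np.zeros_like(pred)
    weights = np.zeros_like(pred)
    had_event = (times <= t) & (events == 1)
    still_at_risk = times > t
    g_minus = np.array([G.survival_at(ti - eps) for ti in times[had_event]])
    dropped = int((g_minus <= 0).sum())
    ok = g_minus > 0
    idx_event = np.flatnonzero(had_event)[ok]
    contrib[idx_event] = (0.0 - pred[idx_event]) ** 2
    weights[idx_event] = 1.0 / g_minus[ok]
    if g_at_t > 0:
        contrib[still_at_risk] = (1.0 - pred[still_at_risk]) ** 2
        weights[still_at_risk] = 1.0 / g_at_t
    else:
        dropped += int(still_at_risk.sum())
    if dropped:
        logger.debug("brier(t=%.1f): %d terms dropped (zero censoring weight)", t, dropped)
    return float((contrib * weights).sum() / len(pred))


def prediction_error_curve(
    model_predictions: dict[str, "callable"], times, events, grid,
) -> pd.DataFrame:
    """Brier(t) over a time grid for several models.

    ``model_predictions`` maps a model name to a callable t -> array of
    predicted S(t|x) for every subject.
    """
    rows = []
    for t in grid:
        row = {"time": float(t)}
        for name, predict in model_predictions.items():
            row[name] = brier(predict(t), times, events, t)
        rows.append(row)
    return pd.DataFrame(rows)


def integrated_brier(predict, times, events, tau: float = 60.0, n_grid: int = 25) -> float:
    """IBS = (1/tau) * integral of Brier(t) over [0, tau], trapezoidal rule.

    ``predict`` is a callable t -> predicted S(t|x) per subject.
    """
    grid = np.linspace(0.0, tau, n_grid)
    scores = np.array([brier(predict(t), times, events, t) for t in grid])
    return float(np.trapezoid(scores, grid) / tau)


# --------------------------------------------------------------------------
# NRI

def _ipcw_status_weights(times, events, horizon):
    """(event weights, non-event weights): IPCW mass for subjects with known
    status at the horizon; censored-before-horizon subjects get 0 in both."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    G = _censoring_km(times, events)
    eps = 1e-12
    w_event = np.zeros(len(times))
    w_non = np.zeros(len(times))
    is_event = (times <= horizon) & (events == 1)
    is_non = times > horizon
    for i in np.flatnonzero(is_event):
        g = G.survival_at(times[i] - eps)
        w_event[i] = 1.0 / g if g > 0 else 0.0
    g_h = G.survival_at(horizon)
    w_non[is_non] = 1.0 / g_h if g_h > 0 else 0.0
    return w_event, w_non


def nri(
    new_risk, old_risk, times, events, horizon: float = 60.0,
    bootstrap: int = 1000, seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Category-free (continuous) NRI at ``horizon`` with IPCW censoring
    weights, plus a seeded percentile-bootstrap CI.

    NRI = P(up|event) - P(down|event) + P(down|non-event) - P(up|non-event),
    where up/down means the new model moves the risk prediction up/down.
    """
    new = np.asarray(new_risk, dtype=float)
    old = np.asarray(old_risk, dtype=float)
    if new.shape != old.shape:
        raise ValueError("models must score the same patients")
    w_event, w_non = _ipcw_status_weights(times, events, horizon)

    def _nri(idx) -> float:
        up = (new[idx] > old[idx]).astype(float)
        down = (new[idx] < old[idx]).astype(float)
        we, wn = w_event[idx], w_non[idx]
        ev = ((up - down) * we).sum() / we.sum() if we.sum() > 0 else 0.0
        non = ((down - up) * wn).sum() / wn.sum() if wn.sum() > 0 else 0.0
        return float(ev + non)

    full = np.arange(len(new))
    estimate = _nri(full)
    rng = np.random.default_rng(seed)
    boots = [_nri(rng.choice(full, size=len(full), replace=True)) for _ in range(bootstrap)]
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return estimate, (float(lo), float(hi))


# --------------------------------------------------------------------------
# decision curves

@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: pd.DataFrame  # columns: one per model + treat_all + treat_none


def decision_curve(
    model_risks: dict[str, np.ndarray], times, events, horizon: float = 60.0,
    thresholds=None,
) -> DecisionCurve:
    """Survival-adapted net benefit over a grid of threshold probabilities.

    For each model and threshold p_t, patients with predicted event risk
    >= p_t are "treated"; the event fraction at the horizon inside that
    group is the KM estimate 1 - S(horizon).  NB = TP/n - (FP/n) p_t/(1-p_t).
    """
    if thresholds is None:
        thresholds = np.arange(0.05, 0.951, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)

    def _nb(positive: np.ndarray, p_t: float) -> float:
        if not positive.any():
            return 0.0
        event_frac = 1.0 - km_estimate(times[positive], events[positive]).survival_at(horizon)
        frac_pos = positive.sum() / n
        tp = frac_pos * event_frac
        fp = frac_pos * (1.0 - event_frac)
        return float(tp - fp * p_t / (1.0 - p_t))

    cols: dict[str, list[float]] = {name: [] for name in model_risks}
    cols["treat_all"] = []
    cols["treat_none"] = []
    all_pos = np.ones(n, dtype=bool)
    for p_t in thresholds:
        for name, risk in model_risks.items():
            cols[name].append(_nb(np.asarray(risk) >= p_t, p_t))
        cols["treat_all"].append(_nb(all_pos, p_t))
        cols["treat_none"].append(0.0)
    nb = pd.DataFrame(cols, index=pd.Index(thresholds, name="threshold"))
    return DecisionCurve(thresholds=thresholds, net_benefit=nb)


# --------------------------------------------------------------------------
# chemotherapy-benefit analysis

def chemo_benefit_analysis(clinical: pd.DataFrame, rs_group) -> pd.DataFrame:
    """Treatment-interaction report: within each stage stratum (II, III,
    II+III) the chemo-vs-no-chemo hazard ratio per RS group and the Wald
    interaction p-value between chemotherapy and RS group.

    ``clinical`` must carry dfs_months, event, chemotherapy and stage;
    ``rs_group`` is the per-patient 'high'/'low' assignment.  Strata where a
    fit is impossible are reported as not estimable.
    """
    rs_group = np.asarray(rs_group)
    rows = []
    strata = {"II": clinical["stage"] == "II",
              "III": clinical["stage"] == "III",
              "II+III": np.ones(len(clinical), dtype=bool)}
    for name, sel in strata.items():
        sel = np.asarray(sel)
        sub = clinical.loc[sel]
        grp = rs_group[sel]
        try:
            res = interaction_cox(sub["dfs_months"], sub["event"],
                                  sub["chemotherapy"], grp)
            p_int = res.interaction_p
            stratum = res.stratum_hr.set_index("group")
        except (ValueError, RuntimeError) as exc:
            logger.warning("stratum %s not estimable: %s", name, exc)
            p_int, stratum = np.nan, None
        for level in ("high", "low"):
            row = {"stage": name, "rs_group": level, "interaction_p": p_int}
            if stratum is not None and level in stratum.index:
                s = stratum.loc[level]
                row.update(n_chemo=int(s["n_treated"]), n_no_chemo=int(s["n_untreated"]),
                           HR=s["HR"], HR_95_lower=s["HR_95_lower"],
                           HR_95_upper=s["HR_95_upper"], p=s["p"])
            else:
                row.update(n_chemo=int(((grp == level) & (sub["chemotherapy"] == 1)).sum()),
                           n_no_chemo=int(((grp == level) & (sub["chemotherapy"] == 0)).sum()),
                           HR=np.nan, HR_95_lower=np.nan, HR_95_upper=np.nan, p=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
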
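"""Nomogram, calibration, IPCW Brier/IBS, NRI, decision curves, chemo benefit."""

import numpy as np
import pandas as pd
import pytest

from periradiomics.prognostic import (
    brier,
    build_nomogram,
    calibration_curve,
    chemo_benefit_analysis,
    decision_curve,
    integrated_brier,
    nri,
    prediction_error_curve,
)
from periradiomics.survival import cox_fit, km_estimate
from periradiomics.synthetic import SimulationConfig, records_to_frame, simulate_clinical


@pytest.fixture(scope="module")
def cohort_fit():
    """A moderately sized simulated cohort with a two-covariate Cox fit."""
    cfg = SimulationConfig(n_patients=250, rng_seed=17)
    df = records_to_frame(simulate_clinical(cfg))
    X = pd.DataFrame({
        "aggressive": (df.latent_class == "aggressive").astype(int),
        "stage3": (df.stage == "III").astype(int),
    })
    fit = cox_fit(X, df.dfs_months, df.event)
    return df, X, fit


class TestNomogram:
    def test_binary_covariate_spans_0_to_100_points(self):
        rng = np.random.default_rng(4)
        n = 150
        x = rng.integers(0, 2, size=n)
        t = rng.exponential(np.where(x == 1, 5.0, 10.0))
        X = pd.DataFrame({"x": x})
        fit = cox_fit(X, t, np.ones(n, int))
        nomo = build_nomogram(fit, X, horizons=(5.0,))
        pts = nomo.points(pd.DataFrame({"x": [0, 1]}))
        assert sorted(pts["total_points"].round(9)) == [0.0, 100.0]

    def test_mean_covariates_predict_baseline(self, cohort_fit):
        df, X, fit = cohort_fit
        nomo = build_nomogram(fit, X, horizons=(36.0,))
        mean_row = pd.DataFrame([X.mean()])
        s0 = nomo.baseline_survival[36.0]
        assert nomo.predict_survival(mean_row, 36.0)[0] == pytest.approx(s0, rel=1e-12)

    def test_round_trip_matches_lifelines_predictions(self, cohort_fit):
        # compare on the fitted step grid, where lifelines' interpolating
        # predictor and the Breslow step function coincide exactly
        df, X, fit = cohort_fit
        grid = fit.fitter.baseline_survival_.index.to_numpy(dtype=float)
        horizons = tuple(np.quantile(grid, [0.25, 0.5, 0.9], method="nearest"))
        nomo = build_nomogram(fit, X, horizons)
        sub = X.iloc[:25]
        direct = fit.fitter.predict_survival_function(sub, times=horizons)
        for h in horizons:
            np.testing.assert_allclose(
                nomo.predict_survival(sub, h), direct.loc[h].to_numpy(), atol=1e-10)

    def test_predictions_monotone_in_total_points(self, cohort_fit):
        df, X, fit = cohort_fit
        nomo = build_nomogram(fit, X, horizons=(60.0,))
        grid = pd.DataFrame({"aggressive": [0, 1, 1], "stage3": [0, 0, 1]})
        pts = nomo.points(grid)["total_points"].to_numpy()
        surv = nomo.predict_survival(grid, 60.0)
        order = np.argsort(pts)
        assert (np.diff(surv[order]) <= 1e-12).all()
        assert ((surv >= 0) & (surv <= 1)).all()


class TestCalibration:
    def test_constant_predictions_single_bin(self, cohort_fit):
        df, X, fit = cohort_fit
        cal = calibration_curve(np.full(len(df), 0.6), df.dfs_months, df.event,
                                horizon=60.0, bootstrap=50, seed=1)
        assert len(cal) == 1

    def test_fixed_seed_reproducible(self, cohort_fit):
        df, X, fit = cohort_fit
        pred = np.linspace(0.1, 0.9, len(df))
        a = calibration_curve(pred, df.dfs_months, df.event, 60.0, bootstrap=100, seed=7)
        b = calibration_curve(pred, df.dfs_months, df.event, 60.0, bootstrap=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_well_calibrated_predictions_sit_on_diagonal(self):
        # predictions equal the generative survival probabilities
        rng = np.random.default_rng(11)
        n = 500
        lam = rng.choice([0.01, 0.02, 0.04], size=n)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0, 120, size=n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        pred = np.exp(-lam * 60.0)
        cal = calibration_curve(pred, times, events, 60.0, bootstrap=200, seed=3)
        inside = ((cal.observed_ci_lower <= cal.predicted)
                  & (cal.predicted <= cal.observed_ci_upper))
        assert inside.mean() >= 0.75


class TestBrier:
    def test_oracle_predictions_zero_score(self):
        times = np.array([2.0, 4.0, 9.0, 11.0])
        events = np.ones(4, int)
        pred_at_6 = (times > 6.0).astype(float)  # exact outcome indicator
        assert brier(pred_at_6, times, events, 6.0) == pytest.approx(0.0)

    def test_constant_half_gives_quarter_without_censoring(self, rng):
        times = rng.exponential(10.0, size=80)
        events = np.ones(80, int)
        for t in (3.0, 8.0, 15.0):
            assert brier(np.full(80, 0.5), times, events, t) == pytest.approx(0.25)

    def test_matches_direct_sum_oracle_under_censoring(self, rng):
        n = 20
        t_ev = rng.exponential(10.0, size=n)
        c = rng.uniform(0, 25, size=n)
        times, events = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        pred = rng.uniform(size=n)
        t0 = 8.0
        G = km_estimate(times, 1 - events)
        total = 0.0
        for i in range(n):
            if times[i] <= t0 and events[i] == 1:
                total += pred[i] ** 2 / G.survival_at(times[i] - 1e-12)
            elif times[i] > t0:
                total += (1 - pred[i]) ** 2 / G.survival_at(t0)
        assert brier(pred, times, events, t0) == pytest.approx(total / n, rel=1e-12)

    def test_matches_scikit_survival(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        n = 120
        t_ev = rng.exponential(10.0, size=n)
        c = rng.uniform(0, 30, size=n)
        times, events = np.minimum(t_ev, c), (t_ev <= c).astype(bool)
        pred = rng.uniform(size=n)
        y = np.array(list(zip(events, times)), dtype=[("e", bool), ("t", float)])
        t0 = np.quantile(times[events], 0.5)
        _, expected = sksurv_metrics.brier_score(y, y, pred.reshape(-1, 1), [t0])
        assert brier(pred, times, events.astype(int), t0) == pytest.approx(
            expected[0], rel=1e-6)

    def test_oracle_has_smallest_integrated_brier(self, rng):
        n = 150
        lam = rng.choice([0.01, 0.05], size=n)
        times = rng.exponential(1.0 / lam)
        events = np.ones(n, int)
        oracle = lambda t: np.exp(-lam * t)
        flat = lambda t: np.full(n, 0.5)
        wrong = lambda t: np.exp(-lam[::-1] * t)
        ibs = {name: integrated_brier(f, times, events, tau=60.0)
               for name, f in [("oracle", oracle), ("flat", flat), ("wrong", wrong)]}
        assert ibs["oracle"] < ibs["flat"]
        assert ibs["oracle"] < ibs["wrong"]

    def test_pec_frame_layout(self, rng):
        times = rng.exponential(10.0, size=40)
        events = np.ones(40, int)
        curves = prediction_error_curve(
            {"flat": lambda t: np.full(40, 0.5)}, times, events, [5.0, 10.0])
        assert list(curves.columns) == ["time", "flat"]
        np.testing.assert_allclose(curves["flat"], 0.25)


class TestNRI:
    def test_identical_models_zero(self, rng):
        r = rng.uniform(size=50)
        t = rng.exponential(10, 50)
        est, _ = nri(r, r, t, np.ones(50, int), horizon=8.0, bootstrap=10, seed=0)
        assert est == 0.0

    def test_hand_counted_toy(self):
        # events: 10 up / 5 down of 50; non-events: 20 down / 10 up of 100
        n_ev, n_ne = 50, 100
        times = np.concatenate([np.full(n_ev, 5.0), np.full(n_ne, 20.0)])
        events = np.concatenate([np.ones(n_ev, int), np.zeros(n_ne, int)])
        old = np.full(n_ev + n_ne, 0.5)
        new = old.copy()
        new[:10] += 0.1; new[10:15] -= 0.1                 # events
        new[n_ev:n_ev + 20] -= 0.1; new[n_ev + 20:n_ev + 30] += 0.1  # non-events
        est, _ = nri(new, old, times, events, horizon=10.0, bootstrap=10, seed=0)
        assert est == pytest.approx((10 - 5) / 50 + (20 - 10) / 100)

    def test_antisymmetry_exact(self, rng):
        n = 60
        t_ev = rng.exponential(10.0, size=n)
        c = rng.uniform(0, 25, size=n)
        times, events = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        a, b = rng.uniform(size=n), rng.uniform(size=n)
        ab, _ = nri(a, b, times, events, 10.0, bootstrap=5, seed=1)
        ba, _ = nri(b, a, times, events, 10.0, bootstrap=5, seed=1)
        assert ab == pytest.approx(-ba, abs=1e-15)

    def test_anti_informative_model_negative(self, rng):
        n = 200
        risk_true = rng.uniform(size=n)
        times = np.where(risk_true > 0.5, 5.0, 50.0) + rng.uniform(0, 1, n)
        events = np.ones(n, int)
        est, _ = nri(1.0 - risk_true, risk_true, times, events, 20.0,
                     bootstrap=10, seed=2)
        assert est < 0


class TestDecisionCurve:
    def test_hand_formula_no_censoring(self):
        # 50 predicted positive of 100; 30 of them events -> NB = 0.3 - 0.2*0.25
        risk = np.concatenate([np.full(50, 0.9), np.full(50, 0.05)])
        times = np.concatenate([np.full(30, 5.0), np.full(20, 100.0), np.full(50, 100.0)])
        events = np.concatenate([np.ones(30, int), np.zeros(70, int)])
        dc = decision_curve({"m": risk}, times, events, horizon=60.0, thresholds=[0.2])
        assert dc.net_benefit["m"].iloc[0] == pytest.approx(0.3 - 0.2 * 0.25)

    def test_treat_none_identically_zero(self, rng):
        times = rng.exponential(20, 80)
        events = rng.integers(0, 2, 80)
        events[0] = 1
        dc = decision_curve({"m": rng.uniform(size=80)}, times, events, 30.0)
        assert (dc.net_benefit["treat_none"] == 0.0).all()

    def test_treat_all_approaches_prevalence_at_tiny_threshold(self, rng):
        n = 300
        times = rng.exponential(30.0, size=n)
        events = np.ones(n, int)
        prevalence = 1.0 - km_estimate(times, events).survival_at(24.0)
        dc = decision_curve({"m": rng.uniform(size=n)}, times, events, 24.0,
                            thresholds=[0.001])
        assert dc.net_benefit["treat_all"].iloc[0] == pytest.approx(prevalence, abs=0.01)

    def test_threshold_domain_validated(self, rng):
        with pytest.raises(ValueError):
            decision_curve({"m": np.array([0.5])}, [1.0], [1], 5.0, thresholds=[0.0])


class TestChemoBenefit:
    def test_recovers_planted_interaction(self):
        cfg = SimulationConfig(n_patients=800, rng_seed=88)
        df = records_to_frame(simulate_clinical(cfg))
        rs_group = np.where(df.latent_class == "aggressive", "low", "high")
        report = chemo_benefit_analysis(df, rs_group)
        combined = report[report.stage == "II+III"].set_index("rs_group")
        # chemotherapy helps the low-RS (aggressive) group ...
        assert combined.loc["low", "HR"] < 1.0
        assert combined.loc["low", "HR_95_upper"] < 1.0
        # ... but not the high-RS group, and the interaction is detected
        assert combined.loc["high", "HR_95_lower"] <= 1.0 <= combined.loc["high", "HR_95_upper"]
        assert combined.loc["low", "interaction_p"] < 0.05

    def test_duplication_leaves_point_estimates_unchanged(self):
        cfg = SimulationConfig(n_patients=300, rng_seed=15)
        df = records_to_frame(simulate_clinical(cfg))
        rs_group = np.where(df.latent_class == "aggressive", "low", "high")
        base = chemo_benefit_analysis(df, rs_group)
        doubled = chemo_benefit_analysis(
            pd.concat([df, df], ignore_index=True), np.concatenate([rs_group, rs_group]))
        for stage in ("II", "III", "II+III"):
            for grp in ("high", "low"):
                a = base[(base.stage == stage) & (base.rs_group == grp)]["HR"].iloc[0]
                b = doubled[(doubled.stage == stage) & (doubled.rs_group == grp)]["HR"].iloc[0]
                # duplication turns every event into a tied pair; under the
                # Efron correction that perturbs estimates by O(1%), so the
                # invariance is near- rather than bit-exact
                assert b == pytest.approx(a, rel=2e-2)
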
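"""KM / log-rank / Cox / concordance / contingency tests vs hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from periradiomics.survival import (
    chi2_or_fisher,
    cox_fit,
    encode_clinical,
    harrell_c,
    interaction_cox,
    km_estimate,
    logrank_test,
    two_sample_t,
    univariate_screen,
)
from periradiomics.synthetic import SimulationConfig, records_to_frame, simulate_clinical


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert (curve.survival == 1.0).all()
        assert curve.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        # censored at 1 and 3, events at 2 and 4: risk sets {2,3,4} then {4}
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert curve.survival_at(2.0) == pytest.approx(2.0 / 3.0)
        assert curve.survival_at(4.0) == pytest.approx(0.0)

    def test_all_events_reduces_to_empirical_survival(self, rng):
        t = rng.exponential(10.0, size=40)
        curve = km_estimate(t, np.ones(40, int))
        for q in (5.0, 10.0, 20.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_greenwood_variance_nonnegative(self, rng):
        t = rng.exponential(10.0, size=50)
        e = rng.integers(0, 2, size=50)
        e[0] = 1
        curve = km_estimate(t, e)
        assert (curve.variance >= -1e-15).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def _mini_logrank(times, events, groups):
    """Tiny self-contained two-group log-rank statistic for permutation use."""
    times, events, groups = map(np.asarray, (times, events, groups))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = ((times == t) & (events == 1))
        n, n1 = at_risk.sum(), (at_risk & (groups == 1)).sum()
        dt, d1 = d.sum(), (d & (groups == 1)).sum()
        o_minus_e += d1 - dt * n1 / n
        if n > 1:
            var += dt * (n1 / n) * (1 - n1 / n) * (n - dt) / (n - 1)
    return o_minus_e ** 2 / var if var > 0 else 0.0


class TestLogrank:
    def test_identical_groups_null(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 0, 1, 1]
        chi2, df, p = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 1, 1, 1, 1, 0]
        g = [0, 1, 0, 1, 0, 1]
        chi2, df, p = logrank_test(t, e, g)
        expected = _mini_logrank(t, e, np.array(g))
        assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_matches_permutation_reference(self, rng):
        t = rng.exponential(10.0, size=14).round(1)
        e = np.ones(14, int)
        g = np.array([0] * 7 + [1] * 7)
        t[g == 1] *= 1.8
        _, _, p = logrank_test(t, e, g)
        obs = _mini_logrank(t, e, g)
        perm = np.array([
            _mini_logrank(t, e, rng.permutation(g)) for _ in range(4000)])
        p_perm = (perm >= obs - 1e-12).mean()
        assert abs(p - p_perm) < 0.04  # within Monte-Carlo error

    def test_group_validation(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


def efron_log_pl(beta, times, events, x):
    """Oracle: Efron partial log-likelihood for one covariate, by direct sums."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        d = tied.sum()
        risk = times >= t
        theta_risk = np.exp(beta * x[risk]).sum()
        theta_tied = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for ell in range(d):
            ll -= np.log(theta_risk - ell / d * theta_tied)
    return ll


class TestCox:
    def test_eight_subject_fit_matches_likelihood_grid(self):
        times = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 8.0, 9.0, 12.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        res = minimize_scalar(lambda b: -efron_log_pl(b, times, events, x),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-4)

    def test_null_covariate_ci_coverage(self):
        # independent covariate: 95% Wald CI covers HR=1 in >=93/100 replicates
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            n = 300
            t = rng.exponential(10.0, size=n)
            c = rng.uniform(0, 25, size=n)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            x = rng.normal(size=n)
            fit = cox_fit(pd.DataFrame({"x": x}), times, events)
            covered += fit.ci_lower[0] <= 1.0 <= fit.ci_upper[0]
        assert covered >= 93

    def test_constant_column_and_no_events_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="event"):
            cox_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [1, 2, 3], [0, 0, 0])


class TestUnivariateScreen:
    def test_null_type_one_error_near_alpha(self):
        hits = trials = 0
        for rep in range(60):
            rng = np.random.default_rng(500 + rep)
            n = 120
            t = rng.exponential(10.0, size=n)
            data = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            selected, _ = univariate_screen(data, t, np.ones(n, int), list("abc"))
            hits += len(selected)
            trials += 3
        assert 0.01 <= hits / trials <= 0.11  # ~5% by construction

    def test_planted_covariate_always_selected(self):
        for rep in range(5):
            rng = np.random.default_rng(rep)
            n = 500
            x = rng.integers(0, 2, size=n)
            t = rng.exponential(np.where(x == 1, 4.0, 12.0))
            data = pd.DataFrame({"planted": x, "noise": rng.normal(size=n)})
            selected, table = univariate_screen(data, t, np.ones(n, int),
                                                ["planted", "noise"])
            assert "planted" in selected

    def test_alpha_zero_selects_nothing(self, rng):
        n = 80
        data = pd.DataFrame({"x": rng.normal(size=n)})
        selected, _ = univariate_screen(data, rng.exponential(5, n),
                                        np.ones(n, int), ["x"], alpha=0.0)
        assert selected == []


class TestHarrellC:
    def test_perfect_concordance(self):
        times = np.array([1.0, 3.0, 5.0, 7.0])
        assert harrell_c(-times, times, np.ones(4, int)) == 1.0

    def test_random_scores_near_half(self, rng):
        t = rng.exponential(10, size=2000)
        assert abs(harrell_c(rng.normal(size=2000), t, np.ones(2000, int)) - 0.5) < 0.03

    def test_matches_pairwise_enumeration(self, rng):
        n = 30
        times = rng.exponential(8.0, size=n)  # continuous: no tied times
        events = rng.integers(0, 2, size=n)
        events[:2] = 1
        risk = rng.integers(0, 4, size=n).astype(float)  # ties in scores
        conc = perm = 0.0
        for i in range(n):
            for j in range(n):
                if times[i] < times[j] and events[i] == 1:
                    perm += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        conc += 0.5
        assert harrell_c(risk, times, events) == pytest.approx(conc / perm, rel=1e-12)


class TestContingencyAndT:
    # printed 2x2 (and 5x2) cohort-comparison tables with their published p-values
    @pytest.mark.parametrize("table,expected_p", [
        ([[163, 254], [123, 199]], 0.805),              # age
        ([[107, 138], [179, 315]], 0.051),              # tumor size
        ([[111, 138], [175, 315]], 0.019),              # Lauren type
        ([[7, 9], [30, 27], [84, 116], [141, 272], [24, 29]], 0.035),  # depth of invasion
        ([[152, 228], [134, 225]], 0.456),              # chemotherapy
    ])
    def test_reproduces_published_p_values(self, table, expected_p):
        stat, p, used = chi2_or_fisher(table)
        assert used == "chi2"
        assert round(p, 3) == expected_p

    def test_independent_table_null(self):
        stat, p, used = chi2_or_fisher([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_fisher_fallback_for_sparse_2x2(self):
        stat, p, used = chi2_or_fisher([[2, 8], [7, 1]])
        assert used == "fisher"
        assert 0 < p < 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_or_fisher([[0, 0], [5, 6]])

    def test_welch_t_detects_shift(self, rng):
        assert two_sample_t(rng.normal(0, 1, 100), rng.normal(2, 3, 100)) < 1e-4
        assert two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


class TestInteraction:
    def test_permuted_treatment_breaks_association(self):
        rng = np.random.default_rng(9)
        cfg = SimulationConfig(n_patients=1500, rng_seed=33)
        df = records_to_frame(simulate_clinical(cfg))
        grp = np.where(df.latent_class == "aggressive", "low", "high")
        permuted = df.chemotherapy.to_numpy().copy()
        for g in ("low", "high"):  # permute within strata
            sel = grp == g
            permuted[sel] = rng.permutation(permuted[sel])
        res = interaction_cox(df.dfs_months, df.event, permuted, grp)
        hrs = res.stratum_hr.set_index("group")["HR"]
        assert abs(np.log(hrs["low"])) < 0.25
        assert abs(np.log(hrs["high"])) < 0.35

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            interaction_cox([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0],
                            ["a", "a", "a", "b"])


def test_encode_clinical_round_trip():
    cfg = SimulationConfig(n_patients=40, rng_seed=3)
    df = records_to_frame(simulate_clinical(cfg))
    enc = encode_clinical(df)
    assert set(enc.columns) >= {"sex", "stage", "t_stage", "n_stage",
                                "age_ge60", "size_ge4cm", "chemotherapy"}
    assert enc["stage"].isin([0, 1]).all()
    assert enc["t_stage"].between(1, 5).all()
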
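"""Survival estimation and hypothesis testing for DFS analyses.

Kaplan-Meier, log-rank, and Cox proportional-hazards fits are delegated to
lifelines (Efron tie correction, Newton-Raphson on the partial likelihood);
this module fixes the package-wide conventions: Wald p-values and
exp(beta +/- 1.96 SE) confidence intervals to match HR (95% CI) reporting,
Pearson chi-square WITHOUT continuity correction (with a Fisher fallback for
2x2 tables when any expected count is below 5), Welch's t-test for continuous
comparisons, and two-sided tests throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "harrell_c",
    "chi2_or_fisher",
    "two_sample_t",
    "interaction_cox",
    "encode_clinical",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance and risk-set sizes."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function, S(t)=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator.  Censored observations tied with events at the
    same time are, by the standard convention, still at risk for that event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate on empty input")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    t_all = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    d = table["observed"].to_numpy(dtype=float)
    n = at_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(n - d > 0, d / (n * (n - d)), 0.0)
    var = surv ** 2 * np.cumsum(incr)
    return SurvivalCurve(event_times=t_all, survival=surv, at_risk=at_risk, variance=var)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-sample log-rank test: (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("logrank_test requires at least 2 groups")
    if np.any(counts == 0):
        raise ValueError("a group has no subjects")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted Cox PH model: Wald inference plus the lifelines fitter for
    baseline-survival prediction downstream."""

    variables: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    fitter: CoxPHFitter = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients, "se": self.se, "HR": self.hr,
            "HR_95_lower": self.ci_lower, "HR_95_upper": self.ci_upper,
            "p": self.p_values,
        }, index=self.variables)


def cox_fit(X: pd.DataFrame, times, events, penalizer: float = 0.0) -> CoxFit:
    """Cox PH fit with Efron tie handling.

    Raises on constant covariate columns or zero events; a monotone
    likelihood / non-convergence is surfaced as a flagged fit (``converged
    = False``), never silent output.  ``penalizer`` adds an optional ridge
    penalty for callers that must stabilize a separated fit (any such
    fallback is the caller's explicit, logged decision).
    """
    X = pd.DataFrame(X).astype(float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("cox_fit requires at least one event")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate columns: {const}")
    df = X.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    converged = not any("convergence" in str(w.message).lower() or
                        "complete separation" in str(w.message).lower() for w in caught)
    beta = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    with np.errstate(over="ignore"):  # huge SE on a flagged fit: CI bound is inf by design
        ci_lo, ci_hi = np.exp(beta - Z_95 * se), np.exp(beta + Z_95 * se)
    return CoxFit(
        variables=list(cph.params_.index),
        coefficients=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_values=2.0 * stats.norm.sf(np.abs(beta / se)),
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        fitter=cph,
    )


def univariate_screen(
    data: pd.DataFrame, times, events, candidates: list[str], alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """One single-covariate Cox fit per candidate; retain Wald p < alpha.

    Returns (selected variables, a log table of coefficients and p-values in
    screening order).
    """
    rows = []
    selected = []
    for var in candidates:
        try:
            fit = cox_fit(data[[var]], times, events)
        except (ValueError, RuntimeError) as exc:
            logger.warning("univariate screen: %s skipped (%s)", var, exc)
            continue
        p = float(fit.p_values[0])
        rows.append({"variable": var, "coef": float(fit.coefficients[0]),
                     "HR": float(fit.hr[0]), "p": p, "selected": p < alpha})
        if p < alpha:
            selected.append(var)
    return selected, pd.DataFrame(rows)


def harrell_c(risk_scores, times, events) -> float:
    """Harrell's C for a RISK score (higher score = earlier expected failure).

    Tied scores count 1/2; pairs rendered incomparable by censoring are
    excluded.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no permissible pairs: no events observed")
    # concordance_index expects higher prediction = longer survival
    return float(concordance_index(np.asarray(times, float), -risk, events))


def chi2_or_fisher(table) -> tuple[float, float, str]:
    """Pearson chi-square WITHOUT continuity correction; Fisher's exact test
    for 2x2 tables when any expected count is below 5.

    Returns (statistic, p, test_used); the statistic is the odds ratio when
    Fisher's test is used.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any() and table.shape == (2, 2):
        odds, p = stats.fisher_exact(table.astype(int))
        return float(odds), float(p), "fisher"
    if (expected < 5).any():
        logger.warning("expected counts below 5 in a %sx%s table; chi-square retained",
                       *table.shape)
    return float(chi2), float(p), "chi2"


def two_sample_t(x, y) -> float:
    """Welch two-sample t-test p-value (two-sided)."""
    return float(stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                                 equal_var=False).pvalue)


@dataclass
class InteractionResult:
    stratum_hr: pd.DataFrame      # per group level: treatment HR, CI, p, cell counts
    interaction_p: float
    fit: CoxFit = field(repr=False, default=None)


def interaction_cox(times, events, treatment, group) -> InteractionResult:
    """Treatment x group interaction: Cox fit with treatment, group and their
    product; Wald p for the product term; within-stratum treatment HRs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    treat = np.asarray(treatment, dtype=int)
    grp = np.asarray(group)
    levels = np.unique(grp)
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {list(levels)}")
    g = (grp == levels[1]).astype(int)
    for tv in (0, 1):
        for gv in (0, 1):
            if not np.any((treat == tv) & (g == gv)):
                raise ValueError(f"empty cell: treatment={tv}, group={levels[gv]}")
    X = pd.DataFrame({"treatment": treat, "group": g, "treatment_x_group": treat * g})
    full = cox_fit(X, times, events)
    p_int = float(full.p_values[full.variables.index("treatment_x_group")])

    rows = []
    for lev in levels:
        sel = grp == lev
        entry = {"group": lev, "n_treated": int(treat[sel].sum()),
                 "n_untreated": int((1 - treat[sel]).sum())}
        try:
            sfit = cox_fit(pd.DataFrame({"treatment": treat[sel]}), times[sel], events[sel])
            entry.update(HR=float(sfit.hr[0]), HR_95_lower=float(sfit.ci_lower[0]),
                         HR_95_upper=float(sfit.ci_upper[0]), p=float(sfit.p_values[0]))
        except (ValueError, RuntimeError) as exc:
            logger.warning("stratum %s treatment HR not estimable: %s", lev, exc)
            entry.update(HR=np.nan, HR_95_lower=np.nan, HR_95_upper=np.nan, p=np.nan)
        rows.append(entry)
    return InteractionResult(stratum_hr=pd.DataFrame(rows), interaction_p=p_int, fit=full)


# --------------------------------------------------------------------------
# clinical covariate encoding shared by the screen / multivariate stages

_BINARY_CODES = {
    "sex": ("F", "M"),
    "differentiation": ("well_moderate", "poor_undiff"),
    "lauren": ("intestinal", "diffuse_mixed"),
    "cea": ("normal", "elevated"),
    "ca199": ("normal", "elevated"),
    "stage": ("II", "III"),
}
_ORDINAL_CODES = {
    "t_stage": ["T1", "T2", "T3", "T4a", "T4b"],
    "n_stage": ["N0", "N1", "N2", "N3a", "N3b"],
}


def encode_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of the clinical covariates for Cox models: binary
    factors to 0/1 (reference level listed first), T/N stage to ordinal
    1..5, age/tumor size dichotomized at the cohort-standard cutoffs
    (60 years, 4 cm), tumor location to an indicator of non-antral site."""
    out = pd.DataFrame(index=table.index)
    for col, (ref, alt) in _BINARY_CODES.items():
        if col in table:
            out[col] = (table[col] == alt).astype(int)
    for col, order in _ORDINAL_CODES.items():
        if col in table:
            out[col] = table[col].map({v: i + 1 for i, v in enumerate(order)}).astype(int)
    if "age" in table:
        out["age_ge60"] = (table["age"] >= 60).astype(int)
    if "tumor_size" in table:
        out["size_ge4cm"] = (table["tumor_size"] >= 4).astype(int)
    if "location" in table:
        out["location_nonantral"] = (table["location"] != "antrum").astype(int)
    if "chemotherapy" in table:
        out["chemotherapy"] = table["chemotherapy"].astype(int)
    return out
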
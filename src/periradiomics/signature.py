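"""The radiomics signature (RS): labels, SVM-RFE selection, scoring.

The RS is the signed distance to a linear soft-margin SVM hyperplane trained
to separate patients who relapsed within a 5-year horizon from those who
did not.  Features are standardized with training-set constants only;
SVM-RFE ranks features by squared hyperplane weight and eliminates the
worst ceil(10%) per iteration; the retained subset size and the SVM cost C
are chosen by inner stratified cross-validated AUC.  The score orientation
is fixed on the training set so that HIGH scores lie on the hyperplane side
with FEWER relapses (high RS = good prognosis), and a score of exactly 0 is
assigned to the low group.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "LabelSet",
    "RSModel",
    "SignatureConfig",
    "Standardization",
    "make_labels",
    "standardize",
    "apply_standardize",
    "train_svm",
    "svm_rfe",
    "select_signature",
    "rs_score",
    "assign_groups",
    "roc_auc",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 60.0
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class LabelSet:
    """Two-class relapse labels: 1 = event within the horizon, 0 = followed
    beyond the horizon event-free.  Patients censored before the horizon
    carry no usable label for classifier training (but are still scored and
    used in every survival analysis)."""

    labels: np.ndarray        # 0/1, arbitrary for unusable rows
    usable: np.ndarray        # bool
    horizon_months: float


def make_labels(dfs_months, events, horizon_months: float = DEFAULT_HORIZON_MONTHS) -> LabelSet:
    t = np.asarray(dfs_months, dtype=float)
    e = np.asarray(events, dtype=int)
    relapse = (e == 1) & (t <= horizon_months)
    beyond = t > horizon_months
    usable = relapse | beyond
    labels = relapse.astype(int)
    return LabelSet(labels=labels, usable=usable, horizon_months=horizon_months)


@dataclass
class Standardization:
    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def to_jsonable(self) -> dict:
        return {"feature_ids": list(self.feature_ids),
                "mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "Standardization":
        return cls(list(d["feature_ids"]), np.asarray(d["mean"]), np.asarray(d["sd"]))


def standardize(train: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """Column-wise z-scoring with training constants; zero-SD columns are
    dropped with a warning (they carry no ranking information)."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    dropped = list(train.columns[~keep])
    if dropped:
        logger.warning("dropping %d zero-variance columns: %s...", len(dropped), dropped[:3])
    cols = train.columns[keep]
    consts = Standardization(list(cols), mean[keep].to_numpy(), sd[keep].to_numpy())
    return apply_standardize(train, consts), consts


def apply_standardize(matrix: pd.DataFrame, consts: Standardization) -> pd.DataFrame:
    missing = [c for c in consts.feature_ids if c not in matrix.columns]
    if missing:
        raise KeyError(f"feature ids missing from matrix: {missing[:5]}")
    sub = matrix[consts.feature_ids]
    return (sub - consts.mean) / consts.sd


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0, kernel: str = "linear",
              class_weight: str | dict | None = "balanced") -> SVC:
    """Soft-margin SVM; with the linear kernel the decision value is w.x + b.

    Class-balanced error weighting is the default: the hyperplane side
    defines the risk groups, and with imbalanced relapse prevalence an
    unweighted fit parks the boundary at the class prior instead of between
    the classes.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(C=C, kernel=kernel, class_weight=class_weight)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def svm_rfe(X: np.ndarray, y: np.ndarray, C: float = 1.0, step_fraction: float = 0.10) -> list[int]:
    """SVM recursive feature elimination.

    Repeatedly fits a linear SVM and removes the ceil(step_fraction x
    remaining) features (at least 1) with the smallest squared weights.
    Returns all column indices ranked best first (the reverse of the
    elimination order; survivors of the last fit are ordered by weight).
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("svm_rfe needs at least 2 features")
    remaining = list(range(n_features))
    eliminated: list[int] = []
    while len(remaining) > 1:
        clf = train_svm(X[:, remaining], y, C=C)
        w2 = (clf.coef_.ravel() ** 2)
        order = np.argsort(w2, kind="stable")  # worst first
        n_drop = max(1, math.ceil(step_fraction * len(remaining)))
        n_drop = min(n_drop, len(remaining) - 1)
        drop_local = sorted(order[:n_drop].tolist())
        for li in reversed(drop_local):
            eliminated.append(remaining.pop(li))
    ranked = remaining + eliminated[::-1]
    return ranked


@dataclass
class SignatureConfig:
    horizon_months: float = DEFAULT_HORIZON_MONTHS
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 5
    max_subset_candidates: int = 16   # RFE-path sizes scanned by inner CV
    seed: int = 0


@dataclass
class RSModel:
    """A trained radiomics signature: feature subset, hyperplane, orientation
    and the training standardization constants needed to score new data."""

    selected_feature_ids: list[str]
    weights: np.ndarray
    bias: float
    orientation: int
    standardization: Standardization
    C: float
    kernel: str = "linear"
    horizon_months: float = DEFAULT_HORIZON_MONTHS
    cv_auc: float = float("nan")
    rfe_ranking: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.selected_feature_ids) != len(self.weights):
            raise ValueError("feature ids and weights disagree in length")
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")

    def to_json(self, path=None) -> str:
        d = {
            "selected_feature_ids": self.selected_feature_ids,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "orientation": self.orientation,
            "standardization": self.standardization.to_jsonable(),
            "C": self.C,
            "kernel": self.kernel,
            "horizon_months": self.horizon_months,
            "cv_auc": self.cv_auc,
            "rfe_ranking": self.rfe_ranking,
            "seed": self.seed,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RSModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        d["standardization"] = Standardization.from_jsonable(d["standardization"])
        d["weights"] = np.asarray(d["weights"])
        return cls(**d)


def _cv_fold_plan(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int, n_repeats: int = 3):
    """Repeated stratified folds with a fold-local RFE ranking each.

    Ranking inside every fold keeps the inner CV honest: a ranking computed
    on all training rows would leak the held-out fold's labels into the
    subset-size choice and grossly inflate the CV AUC.  Repeating the fold
    split damps the winner's-curse variance of the (subset size, C) search
    on small cohorts.
    """
    plan = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            plan.append((tr, te, svm_rfe(X[tr], y[tr], C=1.0)))
    if not plan:
        raise ValueError("no usable CV fold contained both classes")
    return plan


def _cv_auc(X: np.ndarray, y: np.ndarray, plan, C: float, size: int) -> float:
    """Mean held-out AUC over folds, using each fold's own RFE ranking."""
    aucs = []
    for tr, te, ranking in plan:
        cols = ranking[:size]
        clf = train_svm(X[np.ix_(tr, cols)], y[tr], C=C)
        scores = clf.decision_function(X[np.ix_(te, cols)])
        aucs.append(roc_auc(scores, y[te])[0])
    return float(np.mean(aucs))


def _candidate_sizes(n_features: int, step_fraction: float, n_max: int) -> list[int]:
    sizes = []
    n = n_features
    while n > 1:
        sizes.append(n)
        n -= max(1, math.ceil(step_fraction * n))
    sizes.append(1)
    sizes = [s for s in sizes if s >= 2]
    if len(sizes) > n_max:  # geometric subsample of the path, keep ends
        idx = np.unique(np.round(np.linspace(0, len(sizes) - 1, n_max)).astype(int))
        sizes = [sizes[i] for i in idx]
    return sizes


def select_signature(
    features: pd.DataFrame,
    labels: LabelSet,
    config: SignatureConfig | None = None,
) -> RSModel:
    """Fit the full signature on training data: standardize, RFE-rank, choose
    (subset size, C) by inner CV AUC, refit, and fix the orientation so the
    high-score side has the smaller relapse fraction."""
    config = config or SignatureConfig()
    usable = labels.usable
    if usable.sum() < config.n_folds:
        raise ValueError("too few usable (label-complete) training rows")
    y = labels.labels[usable]
    if len(np.unique(y)) < 2:
        raise ValueError("usable training labels contain a single class")
    Xdf = features.loc[np.asarray(usable)]
    Xstd, consts = standardize(Xdf)
    X = Xstd.to_numpy()

    ranking = svm_rfe(X, y, C=1.0)
    sizes = _candidate_sizes(X.shape[1], 0.10, config.max_subset_candidates)
    plan = _cv_fold_plan(X, y, config.n_folds, config.seed)
    best = None
    for C in config.c_grid:
        for size in sizes:
            auc = _cv_auc(X, y, plan, C, size)
            key = (auc, -size, -C)  # ties: prefer smaller subset, then smaller C
            if best is None or key > best[0]:
                best = (key, C, size, auc)
    _, C_best, size_best, auc_best = best
    cols = ranking[:size_best]
    clf = train_svm(X[:, cols], y, C=C_best)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])

    d = X[:, cols] @ w + b
    pos, neg = d > 0, d <= 0
    frac_pos = y[pos].mean() if pos.any() else 0.0
    frac_neg = y[neg].mean() if neg.any() else 1.0
    orientation = 1 if frac_pos < frac_neg else -1

    ids = list(Xstd.columns)
    model = RSModel(
        selected_feature_ids=[ids[c] for c in cols],
        weights=w,
        bias=b,
        orientation=orientation,
        standardization=Standardization(
            [ids[c] for c in cols],
            consts.mean[np.asarray(cols)],
            consts.sd[np.asarray(cols)],
        ),
        C=C_best,
        horizon_months=config.horizon_months,
        cv_auc=auc_best,
        rfe_ranking=[ids[c] for c in ranking],
        seed=config.seed,
    )
    logger.info("signature: %d features, C=%g, inner CV AUC=%.3f, orientation=%+d",
                size_best, C_best, auc_best, orientation)
    return model


def rs_score(model: RSModel, features: pd.DataFrame) -> np.ndarray:
    """RS score = orientation x (w . z + b) with training standardization."""
    Z = apply_standardize(features, model.standardization).to_numpy()
    return model.orientation * (Z @ model.weights + model.bias)


def assign_groups(scores: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """'high' iff score > threshold; a score exactly on the hyperplane is low."""
    return np.where(np.asarray(scores) > threshold, "high", "low")


def roc_auc(scores, labels) -> tuple[float, float, float]:
    """(AUC, sensitivity, specificity) with sensitivity/specificity taken at
    the Youden-optimal threshold.  AUC by trapezoidal integration of the ROC
    curve, which credits ties with 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = int(np.argmax(tpr - fpr))
    return auc, float(tpr[j]), float(1.0 - fpr[j])
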
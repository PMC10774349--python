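"""Held-out evaluation of a fixed ASV set with five non-ensemble classifiers.

The selected signature is scored by classifiers that took no part in its
selection: AdaBoost, Extra Trees, K-nearest neighbours, a multi-layer
perceptron, and LassoCV. Each is evaluated by ROC-AUC in stratified
ten-fold cross-validation on the Z-scored, signature-restricted count
matrix; the headline number is the mean AUC of the five classifiers.
AUC needs only a ranking of the samples, so LassoCV's continuous
regression output is used as a score directly — no threshold is chosen.

Tables report per-fold mean +/- SD per classifier; figures use the ROC of
scores pooled across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core_io import AsvTable, LabelVector
from .refs import _stratified_folds, load_frozen_params, zscore_normalize

__all__ = [
    "VALIDATION_CLASSIFIERS",
    "ClassifierResult",
    "ValidationReport",
    "build_validation_panel",
    "crossval_auc",
    "roc_curve_points",
]

VALIDATION_CLASSIFIERS = ("adaboost", "extra_trees", "kneighbors", "mlp", "lassocv")

_DISPLAY_NAMES = {
    "adaboost": "AdaBoost",
    "extra_trees": "Extra Trees",
    "kneighbors": "KNeighbors",
    "mlp": "MLP",
    "lassocv": "LassoCV",
}


def build_validation_panel(seed: int = 0, params: dict | None = None) -> dict[str, object]:
    """Instantiate the five held-out classifiers with frozen hyperparameters."""
    if params is None:
        params = load_frozen_params()["validation"]
    p = {name: dict(params.get(name) or {}) for name in VALIDATION_CLASSIFIERS}
    return {
        "adaboost": AdaBoostClassifier(random_state=seed, **p["adaboost"]),
        "extra_trees": ExtraTreesClassifier(random_state=seed, **p["extra_trees"]),
        "kneighbors": KNeighborsClassifier(**p["kneighbors"]),
        "mlp": MLPClassifier(random_state=seed, **p["mlp"]),
        "lassocv": LassoCV(random_state=seed, **p["lassocv"]),
    }


def _scores(name: str, fitted, X: np.ndarray) -> np.ndarray:
    if name == "lassocv":
        return np.asarray(fitted.predict(X), dtype=float)
    if hasattr(fitted, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    return fitted.decision_function(X)


@dataclass
class ClassifierResult:
    name: str
    display_name: str
    mean_auc: float
    sd: float
    fold_aucs: list[float]


@dataclass
class ValidationReport:
    """Per-classifier fold AUCs plus pooled ROC points (table + figure shapes)."""

    per_classifier: dict[str, ClassifierResult]
    roc_points: dict[str, list[tuple[float, float]]]
    n_folds: int
    feature_ids: list[str]

    @property
    def ensemble_mean(self) -> float:
        return float(
            np.mean([r.mean_auc for r in self.per_classifier.values()])
        )

    @property
    def best_classifier(self) -> ClassifierResult:
        return max(self.per_classifier.values(), key=lambda r: r.mean_auc)

    def as_rows(self) -> list[dict[str, object]]:
        rows = [
            {
                "classifier": r.display_name,
                "mean_auc": round(r.mean_auc, 3),
                "sd": round(r.sd, 3),
            }
            for r in self.per_classifier.values()
        ]
        rows.append(
            {
                "classifier": "Average",
                "mean_auc": round(self.ensemble_mean, 3),
                "sd": round(float(np.mean([r.sd for r in self.per_classifier.values()])), 3),
            }
        )
        return rows


def crossval_auc(
    table: AsvTable,
    feature_ids: Sequence[str],
    n_folds: int = 10,
    seed: int = 0,
    params: dict | None = None,
    fold_safe_scaling: bool = False,
    labels: LabelVector | None = None,
) -> ValidationReport:
    """Stratified ten-fold AUC of the five held-out classifiers on a feature set.

    The matrix is restricted to ``feature_ids`` and Z-scored (full-matrix
    fit by default, training-fold fit with ``fold_safe_scaling``). Scores
    are the positive-class probability where available, the decision
    function otherwise, and the raw continuous prediction for LassoCV.
    ``labels`` overrides the table's own labels (used e.g. for permutation
    baselines).

    Fold assignment is keyed to sorted sample ids, so the report does not
    depend on sample order in the input files.
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValueError("feature_ids must be non-empty")
    missing = sorted(set(feature_ids) - set(table.asv_ids))
    if missing:
        raise KeyError(f"feature id(s) not present in table: {missing[:10]}")
    sub = table.subset_asvs(feature_ids)
    y = (labels or table.label_vector()).values
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    X_raw = sub.counts.astype(float)
    X_full = None if fold_safe_scaling else zscore_normalize(X_raw)
    folds = _stratified_folds(table.sample_ids, y, n_folds, seed)
    panel = build_validation_panel(seed=seed, params=params)

    fold_aucs: dict[str, list[float]] = {n: [] for n in VALIDATION_CLASSIFIERS}
    pooled_scores: dict[str, np.ndarray] = {
        n: np.zeros(len(y)) for n in VALIDATION_CLASSIFIERS
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train, test in folds:
            if fold_safe_scaling:
                scaler = StandardScaler().fit(X_raw[train])
                Xtr, Xte = scaler.transform(X_raw[train]), scaler.transform(X_raw[test])
            else:
                Xtr, Xte = X_full[train], X_full[test]
            for name in VALIDATION_CLASSIFIERS:
                model = clone(panel[name])
                model.fit(Xtr, y[train])
                s = _scores(name, model, Xte)
                fold_aucs[name].append(float(roc_auc_score(y[test], s)))
                pooled_scores[name][test] = s

    per_classifier = {
        name: ClassifierResult(
            name=name,
            display_name=_DISPLAY_NAMES[name],
            mean_auc=float(np.mean(fold_aucs[name])),
            sd=float(np.std(fold_aucs[name])),
            fold_aucs=fold_aucs[name],
        )
        for name in VALIDATION_CLASSIFIERS
    }
    roc_points = {
        name: roc_curve_points(pooled_scores[name], y)
        for name in VALIDATION_CLASSIFIERS
    }
    return ValidationReport(
        per_classifier=per_classifier,
        roc_points=roc_points,
        n_folds=len(folds),
        feature_ids=feature_ids,
    )


def roc_curve_points(
    scores: np.ndarray, labels: LabelVector | np.ndarray
) -> list[tuple[float, float]]:
    """Empirical ROC as (FPR, TPR) pairs from (0,0) to (1,1).

    Thresholds at every distinct score; the trapezoidal area under the
    returned points equals the Mann-Whitney AUC (ties counted half).
    """
    y = np.asarray(labels.values if isinstance(labels, LabelVector) else labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def trapezoid_auc(points: Sequence[tuple[float, float]]) -> float:
    """Area under a piecewise-linear ROC given as (FPR, TPR) points."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))
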
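"""Recursive ensemble feature selection (REFS).

An ensemble of eight heterogeneous scikit-learn classifiers ranks ASVs by
aggregated importance under stratified ten-fold cross-validation; each
cycle removes the 20% least important features (at least one) until a
single feature remains. The whole schedule is replicated over independent
runs with distinct seeds, and the selected signature is the retained set
of the best-performing cycle of the best-performing run.

Importance aggregation is scale-free: per fold and member, linear models
contribute |coefficient|, tree ensembles their impurity importances, and
bagging the mean over base trees; each member's vector is L1-normalized
before averaging so no member dominates by coefficient magnitude. Cycle
performance is the mean held-out accuracy over folds x members (held-out
ROC-AUC is recorded alongside).

Normalization is a per-feature Z-score fitted on the full matrix before
cross-validation, matching the original procedure; a fold-safe variant
(scaler fitted on training folds only) is available behind a flag and
logs that the default leaks fold statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from joblib import Parallel, delayed
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import (
    LogisticRegression,
    RidgeClassifier,
    SGDClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import AsvTable, LabelVector

logger = logging.getLogger(__name__)

__all__ = [
    "ENSEMBLE_MEMBERS",
    "CycleRecord",
    "EnsembleImportance",
    "EnsembleSpec",
    "RefsResult",
    "elimination_schedule",
    "ensemble_importance",
    "load_frozen_params",
    "run_refs",
    "zscore_normalize",
]

ENSEMBLE_MEMBERS = (
    "sgd",
    "svc",
    "gradient_boosting",
    "random_forest",
    "logistic_regression",
    "passive_aggressive",
    "ridge",
    "bagging",
)

_LINEAR_MEMBERS = frozenset(
    {"sgd", "svc", "logistic_regression", "passive_aggressive", "ridge"}
)


def load_frozen_params() -> dict:
    """Load the versioned classifier-hyperparameter config shipped with the package."""
    ref = resources.files("refsig.data").joinpath("ensemble_params.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class EnsembleSpec:
    """The eight-member selection ensemble with frozen hyperparameters."""

    params: dict = field(default_factory=lambda: load_frozen_params()["ensemble"])
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(ENSEMBLE_MEMBERS) - set(self.params)
        if missing:
            raise ValueError(f"ensemble config missing member(s): {sorted(missing)}")
        if len(self.params) != len(ENSEMBLE_MEMBERS):
            extra = set(self.params) - set(ENSEMBLE_MEMBERS)
            raise ValueError(f"unexpected ensemble member(s): {sorted(extra)}")

    def build(self) -> dict[str, object]:
        """Instantiate fresh estimators, all seeded from ``self.seed``."""
        p = {name: dict(self.params.get(name) or {}) for name in ENSEMBLE_MEMBERS}
        return {
            "sgd": SGDClassifier(random_state=self.seed, **p["sgd"]),
            "svc": SVC(random_state=self.seed, **{"kernel": "linear", **p["svc"]}),
            "gradient_boosting": GradientBoostingClassifier(
                random_state=self.seed, **p["gradient_boosting"]
            ),
            "random_forest": RandomForestClassifier(
                random_state=self.seed, **p["random_forest"]
            ),
            "logistic_regression": LogisticRegression(**p["logistic_regression"]),
            # PA-I in its SGD parametrization (hinge loss, no penalty,
            # pa1 learning rate with aggressiveness C = eta0)
            "passive_aggressive": SGDClassifier(
                random_state=self.seed,
                **{
                    "loss": "hinge",
                    "penalty": None,
                    "learning_rate": "pa1",
                    "eta0": 1.0,
                    **p["passive_aggressive"],
                },
            ),
            "ridge": RidgeClassifier(**p["ridge"]),
            "bagging": BaggingClassifier(random_state=self.seed, **p["bagging"]),
        }


# ---------------------------------------------------------------------------
# normalization


def zscore_normalize(table_or_matrix: AsvTable | np.ndarray) -> np.ndarray:
    """Per-feature Z-score over the whole matrix; constant columns map to zeros."""
    if isinstance(table_or_matrix, AsvTable):
        X = table_or_matrix.counts.astype(float)
    else:
        X = np.asarray(table_or_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Z-score normalization needs at least 2 samples")
    # StandardScaler uses the population sd and already maps sd=0 columns to 0
    return StandardScaler().fit_transform(X)


# ---------------------------------------------------------------------------
# importance


def _member_importance(name: str, fitted) -> np.ndarray:
    if name in _LINEAR_MEMBERS:
        return np.abs(np.asarray(fitted.coef_).ravel())
    if name == "bagging":
        n_features = fitted.n_features_in_
        acc = np.zeros(n_features)
        for est, feats in zip(fitted.estimators_, fitted.estimators_features_):
            acc[feats] += est.feature_importances_
        return acc / len(fitted.estimators_)
    return np.asarray(fitted.feature_importances_)


def _l1(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        return np.full_like(v, 1.0 / len(v))
    return v / total


def _stratified_folds(
    sample_ids: Sequence[str], y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds keyed to sorted sample ids, so file order is irrelevant.

    Reduces the fold count to the minority-class size when necessary (with
    a warning); fails below 2 samples per class.
    """
    y = np.asarray(y)
    min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
    if min_class < 2:
        raise ValueError("need at least 2 samples in each class for cross-validation")
    effective = n_folds
    if min_class < n_folds:
        logger.warning(
            "reducing fold count from %d to %d (minority class size)", n_folds, min_class
        )
        effective = min_class
    order = np.argsort(np.asarray(sample_ids, dtype=object))
    skf = StratifiedKFold(n_splits=effective, shuffle=True, random_state=seed % (2**32))
    folds = []
    for train_sorted, test_sorted in skf.split(order.reshape(-1, 1), y[order]):
        folds.append((order[train_sorted], order[test_sorted]))
    return folds


@dataclass
class EnsembleImportance:
    """Aggregated per-feature importance plus held-out fold scores."""

    importances: dict[str, float]  # asv_id -> mean L1-normalized importance
    fold_accuracies: np.ndarray  # shape (n_folds, n_members)
    fold_aucs: np.ndarray  # shape (n_folds, n_members)
    member_names: tuple[str, ...] = ENSEMBLE_MEMBERS

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracies.mean(axis=1).std())

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())


def _continuous_scores(fitted, X: np.ndarray) -> np.ndarray:
    if hasattr(fitted, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    return fitted.decision_function(X)


def ensemble_importance(
    X: np.ndarray,
    y: LabelVector | np.ndarray,
    feature_ids: Sequence[str],
    spec: EnsembleSpec,
    n_folds: int = 10,
    sample_ids: Sequence[str] | None = None,
) -> EnsembleImportance:
    """Mean L1-normalized importance over stratified folds x ensemble members.

    Per fold each member is fitted on the training split; its per-feature
    importance vector is L1-normalized and its held-out accuracy and
    ROC-AUC are recorded. The returned importances are the mean over all
    (fold, member) pairs and sum to one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y.values if isinstance(y, LabelVector) else y, dtype=int)
    if sample_ids is None:
        sample_ids = [f"s{i:06d}" for i in range(len(y))]
    if X.shape[1] != len(feature_ids):
        raise ValueError("feature_ids length must match the number of columns")
    folds = _stratified_folds(sample_ids, y, n_folds, spec.seed)
    members = spec.build()

    importance_sum = np.zeros(X.shape[1])
    accs = np.zeros((len(folds), len(ENSEMBLE_MEMBERS)))
    aucs = np.zeros((len(folds), len(ENSEMBLE_MEMBERS)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fi, (train, test) in enumerate(folds):
            for mi, name in enumerate(ENSEMBLE_MEMBERS):
                model = clone(members[name])
                model.fit(X[train], y[train])
                importance_sum += _l1(_member_importance(name, model))
                accs[fi, mi] = model.score(X[test], y[test])
                aucs[fi, mi] = roc_auc_score(y[test], _continuous_scores(model, X[test]))
    mean_importance = importance_sum / (len(folds) * len(ENSEMBLE_MEMBERS))
    return EnsembleImportance(
        importances=dict(zip(feature_ids, mean_importance.tolist())),
        fold_accuracies=accs,
        fold_aucs=aucs,
    )


# ---------------------------------------------------------------------------
# elimination schedule


def elimination_schedule(n_start: int) -> list[int]:
    """Feature counts per cycle: n -> n - max(1, floor(0.2 n)), down to 1."""
    if n_start < 1:
        raise ValueError("n_start must be >= 1")
    schedule = [n_start]
    while schedule[-1] > 1:
        n = schedule[-1]
        schedule.append(n - max(1, n // 5))
    return schedule


# ---------------------------------------------------------------------------
# the full recursion


@dataclass
class CycleRecord:
    """One elimination cycle of one run."""

    cycle_index: int
    retained_asv_ids: list[str]  # descending importance order
    mean_score: float  # held-out accuracy, folds x members
    score_sd: float
    mean_auc: float
    fold_scores: list[float]  # per-fold member-averaged accuracy

    @property
    def n_features(self) -> int:
        return len(self.retained_asv_ids)


@dataclass
class RefsResult:
    runs: list[list[CycleRecord]]
    run_seeds: list[int]
    best_run: int
    best_cycle: int
    selected_asv_ids: list[str]
    importance_rank: dict[str, int]  # asv_id -> 1-based final rank

    @property
    def best_record(self) -> CycleRecord:
        return self.runs[self.best_run][self.best_cycle]

    def score_curve(self) -> list[tuple[int, int, int, float, float]]:
        """(run, cycle, n_features, mean_score, sd) rows for every cycle."""
        return [
            (ri, rec.cycle_index, rec.n_features, rec.mean_score, rec.score_sd)
            for ri, run in enumerate(self.runs)
            for rec in run
        ]


def _single_run(
    X: np.ndarray,
    y: np.ndarray,
    asv_ids: list[str],
    sample_ids: list[str],
    params: dict,
    run_seed: int,
    n_folds: int,
) -> list[CycleRecord]:
    spec = EnsembleSpec(params=params, seed=run_seed)
    retained = np.arange(len(asv_ids))
    records: list[CycleRecord] = []
    cycle = 0
    while True:
        ids = [asv_ids[j] for j in retained]
        imp = ensemble_importance(
            X[:, retained], y, ids, spec, n_folds=n_folds, sample_ids=sample_ids
        )
        vals = np.array([imp.importances[a] for a in ids])
        # descending importance; ties broken by current column order (stable)
        order = np.argsort(-vals, kind="stable")
        records.append(
            CycleRecord(
                cycle_index=cycle,
                retained_asv_ids=[ids[k] for k in order],
                mean_score=imp.mean_accuracy,
                score_sd=imp.accuracy_sd,
                mean_auc=imp.mean_auc,
                fold_scores=imp.fold_accuracies.mean(axis=1).tolist(),
            )
        )
        n = len(retained)
        if n == 1:
            break
        keep = n - max(1, n // 5)
        retained = retained[np.sort(order[:keep])]
        cycle += 1
    return records


def _best_cycle_index(run: list[CycleRecord]) -> int:
    # max mean_score; ties -> fewer features (later cycles have fewer)
    best = 0
    for i, rec in enumerate(run):
        if rec.mean_score > run[best].mean_score or (
            rec.mean_score == run[best].mean_score
            and rec.n_features < run[best].n_features
        ):
            best = i
    return best


def run_refs(
    table: AsvTable,
    spec: EnsembleSpec | None = None,
    n_runs: int = 30,
    n_folds: int = 10,
    seed: int = 0,
    n_jobs: int = 1,
    fold_safe_scaling: bool = False,
) -> RefsResult:
    """Run the full recursive elimination and select the signature.

    Each run gets an independent derived seed (``seed + run index``); runs
    may execute concurrently but are merged by run index, so the result is
    deterministic under a fixed master seed. The best cycle of a run is its
    highest mean held-out accuracy (ties favour fewer features); the best
    run is the one with the highest best-cycle score (ties favour the lower
    run index). The selected signature is that cycle's retained set, ranked
    by descending ensemble importance.

    By default the Z-score is fitted once on the full matrix before
    cross-validation, as in the original procedure; ``fold_safe_scaling``
    refits the scaler inside every training fold instead.
    """
    if spec is None:
        spec = EnsembleSpec()
    y = table.label_vector().values
    if fold_safe_scaling:
        X = table.counts.astype(float)
    else:
        logger.warning(
            "Z-score fitted on the full matrix before cross-validation "
            "(faithful to the original procedure; leaks fold statistics — "
            "pass fold_safe_scaling=True for train-only scaling)"
        )
        X = zscore_normalize(table)
    run_seeds = [seed + r for r in range(n_runs)]
    runner = _single_run_fold_safe if fold_safe_scaling else _single_run
    runs = Parallel(n_jobs=n_jobs)(
        delayed(runner)(
            X, y, table.asv_ids, table.sample_ids, spec.params, rs, n_folds
        )
        for rs in run_seeds
    )
    runs = list(runs)

    best_cycles = [_best_cycle_index(run) for run in runs]
    best_run = 0
    for ri in range(1, n_runs):
        if runs[ri][best_cycles[ri]].mean_score > runs[best_run][best_cycles[best_run]].mean_score:
            best_run = ri
    best_cycle = best_cycles[best_run]
    selected = runs[best_run][best_cycle].retained_asv_ids
    return RefsResult(
        runs=runs,
        run_seeds=run_seeds,
        best_run=best_run,
        best_cycle=best_cycle,
        selected_asv_ids=list(selected),
        importance_rank={a: i + 1 for i, a in enumerate(selected)},
    )


def _single_run_fold_safe(
    X_raw: np.ndarray,
    y: np.ndarray,
    asv_ids: list[str],
    sample_ids: list[str],
    params: dict,
    run_seed: int,
    n_folds: int,
) -> list[CycleRecord]:
    """Variant of :func:`_single_run` scaling inside each training fold."""
    spec = EnsembleSpec(params=params, seed=run_seed)
    retained = np.arange(len(asv_ids))
    records: list[CycleRecord] = []
    cycle = 0
    while True:
        ids = [asv_ids[j] for j in retained]
        Xr = X_raw[:, retained]
        folds = _stratified_folds(sample_ids, y, n_folds, spec.seed)
        members = spec.build()
        importance_sum = np.zeros(Xr.shape[1])
        accs = np.zeros((len(folds), len(ENSEMBLE_MEMBERS)))
        aucs = np.zeros((len(folds), len(ENSEMBLE_MEMBERS)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for fi, (train, test) in enumerate(folds):
                scaler = StandardScaler().fit(Xr[train])
                Xtr, Xte = scaler.transform(Xr[train]), scaler.transform(Xr[test])
                for mi, name in enumerate(ENSEMBLE_MEMBERS):
                    model = clone(members[name])
                    model.fit(Xtr, y[train])
                    importance_sum += _l1(_member_importance(name, model))
                    accs[fi, mi] = model.score(Xte, y[test])
                    aucs[fi, mi] = roc_auc_score(
                        y[test], _continuous_scores(model, Xte)
                    )
        vals = importance_sum / (len(folds) * len(ENSEMBLE_MEMBERS))
        order = np.argsort(-vals, kind="stable")
        records.append(
            CycleRecord(
                cycle_index=cycle,
                retained_asv_ids=[ids[k] for k in order],
                mean_score=float(accs.mean()),
                score_sd=float(accs.mean(axis=1).std()),
                mean_auc=float(aucs.mean()),
                fold_scores=accs.mean(axis=1).tolist(),
            )
        )
        n = len(retained)
        if n == 1:
            break
        keep = n - max(1, n // 5)
        retained = retained[np.sort(order[:keep])]
        cycle += 1
    return records
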
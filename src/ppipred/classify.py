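"""SVM and random-forest classifiers over pair feature vectors.

Both learners output a probability that a pair interacts, which is used
as the interaction score.  The SVM uses an RBF kernel with features
standardized and (cost, gamma) chosen by internal cross-validated grid
search; the random forest is a seeded ensemble of 500 trees.  Consensus
predictions — pairs scored above threshold by *both* learners — serve
as the conservative genome-wide call set.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import evaluate
from .pairs import MISSING, PairKey, is_missing
from .pair_features import PairFeatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "PredictionRecord",
    "train",
    "predict_scores",
    "consensus",
    "calibrate_threshold",
    "feature_importance",
    "cross_validate",
    "summarize_cv",
]

LEARNERS = ("svm_rbf", "random_forest")


@dataclass(frozen=True)
class TrainingConfig:
    """Learner choice and tuning knobs.

    ``svm_cost_grid`` and ``svm_gamma_scale`` span the RBF grid search
    (gamma values are ``scale / n_features``); ``rf_trees`` sets the
    forest size.  All stochastic stages derive from ``seed``.
    """

    learner: str = "random_forest"
    svm_cost_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_scale: tuple[float, ...] = (0.1, 1.0, 10.0)
    rf_trees: int = 500
    tune_folds: int = 5
    cv_folds: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}; choose from {LEARNERS}")
        if not self.svm_cost_grid or not self.svm_gamma_scale:
            raise ValueError("SVM tuning grids must be non-empty")
        if self.cv_folds < 2 or self.tune_folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


@dataclass
class TrainedModel:
    """A fitted learner bound to the feature layout it was trained on."""

    kind: str
    estimator: object
    layout: tuple[str, ...]
    fingerprint: str
    seed: int
    grid_winner: dict | None = None

    def check_layout(self, layout: Sequence[str]) -> None:
        if layout_fingerprint(layout) != self.fingerprint:
            raise ValueError(
                "feature layout fingerprint mismatch: the model was trained "
                "on a different vector schema"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """Per-pair scores from both learners plus the consensus call."""

    pair: PairKey
    svm_score: float = MISSING
    rf_score: float = MISSING
    consensus: bool = False

    def __post_init__(self):
        for s in (self.svm_score, self.rf_score):
            if not is_missing(s) and not (0.0 <= s <= 1.0):
                raise ValueError(f"score outside [0, 1]: {s}")


def layout_fingerprint(layout: Sequence[str]) -> str:
    return hashlib.sha256("\x1f".join(layout).encode()).hexdigest()[:16]


def _design_matrix(vectors: Sequence[PairFeatureVector]) -> tuple[np.ndarray, tuple[str, ...]]:
    if not vectors:
        raise ValueError("no vectors supplied")
    layout = vectors[0].layout
    for v in vectors:
        if v.layout != layout:
            raise ValueError("vectors with heterogeneous layouts")
    X = np.vstack([v.values for v in vectors])
    return X, layout


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise ValueError(f"labels must contain both classes 0 and 1, got {sorted(classes)}")
    return y


def _fit_estimator(X: np.ndarray, y: np.ndarray, config: TrainingConfig,
                   learner: str) -> tuple[object, dict | None]:
    if learner == "random_forest":
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features="sqrt",
            random_state=config.seed % (2**31),
            n_jobs=1,
        )
        rf.fit(X, y)
        return rf, None
    d = X.shape[1]
    grid = {
        "svc__C": list(config.svm_cost_grid),
        "svc__gamma": [s / d for s in config.svm_gamma_scale],
    }
    folds = min(config.tune_folds, int(np.bincount(y).min()))
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", probability=True, random_state=config.seed % (2**31))),
    ])
    search = GridSearchCV(
        pipe,
        grid,
        cv=StratifiedKFold(max(folds, 2), shuffle=True, random_state=config.seed % (2**31)),
        scoring="accuracy",
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    winner = {"C": search.best_params_["svc__C"], "gamma": search.best_params_["svc__gamma"]}
    return search.best_estimator_, winner


def train(vectors: Sequence[PairFeatureVector], labels, config: TrainingConfig) -> TrainedModel:
    """Fit the configured learner on complete pair vectors.

    Raises on incomplete vectors or single-class labels.
    """
    incomplete = sum(1 for v in vectors if not v.complete)
    if incomplete:
        raise ValueError(
            f"{incomplete} incomplete vector(s): apply filter_complete before training"
        )
    X, layout = _design_matrix(vectors)
    y = _check_labels(labels)
    if len(y) != len(vectors):
        raise ValueError("labels not aligned with vectors")
    estimator, winner = _fit_estimator(X, y, config, config.learner)
    return TrainedModel(
        kind=config.learner,
        estimator=estimator,
        layout=layout,
        fingerprint=layout_fingerprint(layout),
        seed=config.seed,
        grid_winner=winner,
    )


def predict_scores(model: TrainedModel,
                   vectors: Sequence[PairFeatureVector]) -> list[tuple[PairKey, float]]:
    """Interaction probability for each pair; incomplete vectors get MISSING."""
    if not vectors:
        return []
    model.check_layout(vectors[0].layout)
    out: list[tuple[PairKey, float]] = []
    complete_idx = [i for i, v in enumerate(vectors) if v.complete]
    scores = np.full(len(vectors), MISSING)
    if complete_idx:
        X = np.vstack([vectors[i].values for i in complete_idx])
        if vectors[complete_idx[0]].layout != model.layout:
            raise ValueError("feature layout mismatch")
        proba = model.estimator.predict_proba(X)
        pos_col = list(model.estimator.classes_).index(1)
        scores[complete_idx] = proba[:, pos_col]
    for v, s in zip(vectors, scores):
        out.append((v.pair, float(s) if not np.isnan(s) else MISSING))
    return out


def consensus(predictions: Iterable[PredictionRecord], threshold: float) -> set[PairKey]:
    """Pairs called by both learners at the threshold (score >= t for both)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    out = set()
    for rec in predictions:
        if is_missing(rec.svm_score) or is_missing(rec.rf_score):
            continue
        if rec.svm_score >= threshold and rec.rf_score >= threshold:
            out.add(rec.pair)
    return out


def make_prediction_records(
    svm_scores: Iterable[tuple[PairKey, float]],
    rf_scores: Iterable[tuple[PairKey, float]],
    threshold: float,
) -> list[PredictionRecord]:
    """Merge per-learner score lists into consensus-annotated records."""
    svm = dict(svm_scores)
    rf = dict(rf_scores)
    records = []
    for pair in sorted(set(svm) | set(rf)):
        s, r = svm.get(pair, MISSING), rf.get(pair, MISSING)
        cons = (
            not is_missing(s) and not is_missing(r)
            and s >= threshold and r >= threshold
        )
        records.append(PredictionRecord(pair=pair, svm_score=s, rf_score=r, consensus=cons))
    return records


def calibrate_threshold(
    predictions: Sequence[PredictionRecord], target_count: int
) -> tuple[float, int]:
    """Smallest observed threshold whose consensus set has <= target pairs.

    The candidate grid is the set of observed consensus-eligible scores
    (min of the two learners' scores over pairs where both are present).
    Returns ``(threshold, achieved_count)``; a target at least as large
    as the eligible pool returns threshold 0 with a warning.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    mins = sorted(
        min(r.svm_score, r.rf_score)
        for r in predictions
        if not (is_missing(r.svm_score) or is_missing(r.rf_score))
    )
    n = len(mins)
    if target_count >= n:
        logger.warning("target %d >= %d eligible pairs: threshold 0 passes everything",
                       target_count, n)
        return 0.0, n
    grid = sorted(set(mins))
    for t in grid:
        # pairs with min score >= t
        count = n - np.searchsorted(mins, t, side="left")
        if count <= target_count:
            return float(t), int(count)
    logger.warning("no observed threshold reaches the target (massive score ties)")
    return float(grid[-1]), int(n - np.searchsorted(mins, grid[-1], side="left"))


def feature_importance(
    vectors: Sequence[PairFeatureVector],
    labels,
    config: TrainingConfig,
    n_repeats: int = 20,
    holdout_fraction: float = 0.3,
) -> list[tuple[str, float]]:
    """Permutation importance: mean decrease in held-out accuracy.

    The data are split once (stratified, seeded), the learner fitted on
    the training part, and each feature permuted ``n_repeats`` times on
    the held-out part.  Ties are broken by feature name.
    """
    X, layout = _design_matrix(vectors)
    y = _check_labels(labels)
    rs = config.seed % (2**31)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=rs
    )
    estimator, _ = _fit_estimator(X_tr, y_tr, config, config.learner)
    result = permutation_importance(
        estimator, X_te, y_te, scoring="accuracy", n_repeats=n_repeats, random_state=rs
    )
    ranked = sorted(
        zip(layout, result.importances_mean),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return [(name, float(imp)) for name, imp in ranked]


def cross_validate(
    vectors: Sequence[PairFeatureVector],
    labels,
    folds: int,
    repeats: int,
    config: TrainingConfig,
    threshold: float = 0.5,
) -> list[evaluate.MetricsReport]:
    """Repeated stratified k-fold cross-validation.

    Each repeat pools the out-of-fold scores over its folds and reports
    the full metric battery at ``threshold``.  Stratification guarantees
    both classes in every fold.  Same seed, same splits.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, layout = _design_matrix(vectors)
    y = _check_labels(labels)
    reports = []
    for r in range(repeats):
        skf = StratifiedKFold(folds, shuffle=True,
                              random_state=(config.seed + r) % (2**31))
        scores = np.full(len(y), np.nan)
        for train_idx, test_idx in skf.split(X, y):
            est, _ = _fit_estimator(X[train_idx], y[train_idx], config, config.learner)
            proba = est.predict_proba(X[test_idx])
            pos_col = list(est.classes_).index(1)
            scores[test_idx] = proba[:, pos_col]
        reports.append(evaluate.report(scores, y, threshold=threshold))
    return reports


def summarize_cv(reports: Sequence[evaluate.MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation of the headline metrics across repeats."""
    out = {}
    for name in ("accuracy", "sensitivity", "specificity", "precision", "auc", "auc50"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0)
    return out
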
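"""Cross-validated stress classification and its evaluation metrics.

Five classifier families are supported — SVM, Gaussian Naive Bayes,
k-nearest neighbours (Euclidean distance), L2 logistic regression and a
one-hidden-layer sigmoid MLP trained on squared error — each with a
small hyperparameter grid searched *inside* the training partition of
every outer fold (nested cross-validation), so test folds never touch
model selection.  Features are z-scaled with training-fold statistics
only.

Evaluation follows the pooled out-of-fold protocol: stratified 10-fold
cross-validation predicts every sample exactly once, and the metrics —
accuracy (%), Cohen's kappa, support-weighted F-measure, mean absolute
probability error (MAE) and its root-mean-square counterpart (RMAE) —
are computed from the pooled predictions.  The per-fold mean accuracy is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("SVM", "NB", "KNN", "LR", "MLP")

#: Default hyperparameter grids (the classifier names are pipeline steps,
#: so grid keys carry the ``clf__`` prefix).
DEFAULT_GRIDS: dict[str, list[dict] | dict] = {
    "SVM": [
        {"clf__kernel": ["linear"], "clf__C": [0.1, 1.0, 10.0, 100.0]},
        {
            "clf__kernel": ["rbf"],
            "clf__C": [0.1, 1.0, 10.0, 100.0],
            "clf__gamma": ["scale", 0.01, 0.1],
        },
    ],
    "NB": {},
    "KNN": {"clf__n_neighbors": [1, 3, 5, 7]},
    "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "MLP": {"clf__hidden_layer_sizes": [(4,), (8,), (16,)]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid."""

    kind: str
    grid: list[dict] | dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"classifier kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )

    @classmethod
    def default(cls, kind: str) -> "ClassifierSpec":
        return cls(kind=kind, grid=DEFAULT_GRIDS[kind])

    @classmethod
    def default_suite(cls) -> list["ClassifierSpec"]:
        return [cls.default(kind) for kind in CLASSIFIER_KINDS]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    inner_folds: int = 3
    nested: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass(frozen=True)
class Metrics:
    accuracy: float  # percent
    kappa: float
    f_measure: float  # support-weighted across classes
    mae: float
    rmae: float
    f1_positive: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "f_measure": self.f_measure,
            "mae": self.mae,
            "rmae": self.rmae,
            "f1_positive": self.f1_positive,
        }


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one classifier on one feature set."""

    spec: ClassifierSpec
    metrics: Metrics
    confusion: np.ndarray  # rows true (0, 1), cols predicted (0, 1)
    fold_accuracies: list[float]
    predictions: pd.DataFrame  # index: sample ids; y_true, y_pred, p_stress

    @property
    def fold_mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def build_estimator(spec: ClassifierSpec, seed: int) -> Pipeline:
    """Scaler + classifier pipeline for one family.

    The MLP uses a single hidden layer with logistic activation — the
    squared-error/backpropagation framing — and LBFGS, which is robust
    on the small cohorts involved.
    """
    if spec.kind == "SVM":
        clf = SVC(probability=True, random_state=seed)
    elif spec.kind == "NB":
        clf = GaussianNB()
    elif spec.kind == "KNN":
        clf = KNeighborsClassifier(metric="euclidean")
    elif spec.kind == "LR":
        clf = LogisticRegression(max_iter=2000)
    elif spec.kind == "MLP":
        clf = MLPClassifier(
            hidden_layer_sizes=(8,),
            activation="logistic",
            solver="lbfgs",
            max_iter=2000,
            random_state=seed,
        )
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.kind)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, p_stress: np.ndarray
) -> Metrics:
    """Evaluation metrics from pooled predictions.

    ``p_stress`` is the predicted probability of the stress class.  The
    probability errors are ``1 - p(true class)`` per sample: MAE is
    their mean, RMAE the root of their mean square.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    p_stress = np.asarray(p_stress, dtype=float)
    if not (len(y_true) == len(y_pred) == len(p_stress)):
        raise ValueError("y_true, y_pred and p_stress must have equal length")
    if np.any((p_stress < 0) | (p_stress > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = len(y_true)
    if n == 0:
        raise ValueError("cannot compute metrics on zero samples")

    accuracy = 100.0 * float(np.mean(y_true == y_pred))

    # Cohen's kappa from the 2x2 confusion marginals.
    po = float(np.mean(y_true == y_pred))
    pe = sum(
        float(np.mean(y_true == c)) * float(np.mean(y_pred == c)) for c in (0, 1)
    )
    kappa = 1.0 if po == 1.0 else (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0

    def _f1(cls: int) -> float:
        tp = float(np.sum((y_true == cls) & (y_pred == cls)))
        fp = float(np.sum((y_true != cls) & (y_pred == cls)))
        fn = float(np.sum((y_true == cls) & (y_pred != cls)))
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom > 0 else 0.0

    support = np.array([np.sum(y_true == 0), np.sum(y_true == 1)], dtype=float)
    f_weighted = float(np.average([_f1(0), _f1(1)], weights=support))

    p_true = np.where(y_true == 1, p_stress, 1.0 - p_stress)
    err = 1.0 - p_true
    mae = float(np.mean(np.abs(err)))
    rmae = float(np.sqrt(np.mean(err**2)))
    return Metrics(
        accuracy=accuracy,
        kappa=float(kappa),
        f_measure=f_weighted,
        mae=mae,
        rmae=rmae,
        f1_positive=_f1(1),
    )


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)):
        cm[t, p] += 1
    return cm


def _outer_splitter(cv: CVConfig):
    if cv.stratified:
        return StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    return KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)


def _has_grid(spec: ClassifierSpec) -> bool:
    grid = spec.grid
    return bool(grid) if isinstance(grid, dict) else any(grid)


def _grid_search(
    estimator: Pipeline,
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
):
    """Grid-search the spec's hyperparameters on (X, y) only."""
    inner_folds = min(cv.inner_folds, int(np.min(np.bincount(y))))
    inner_folds = max(inner_folds, 2)
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=cv.seed)
    search = GridSearchCV(
        clone(estimator), spec.grid, cv=inner, scoring="accuracy", n_jobs=1
    )
    search.fit(X, y)
    return search


def _fit_fold_model(
    estimator: Pipeline,
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cv: CVConfig,
):
    """Fit one training fold, grid-searching inside it if a grid exists."""
    if not (_has_grid(spec) and cv.nested):
        model = clone(estimator)
        model.fit(X_train, y_train)
        return model
    return _grid_search(estimator, spec, X_train, y_train, cv).best_estimator_


def cross_validate(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    cv: CVConfig = CVConfig(),
) -> CVResult:
    """Stratified k-fold evaluation with pooled out-of-fold predictions.

    Every sample is predicted exactly once by a model that never saw it
    (nor its fold's labels) during training or hyperparameter search.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("features and labels are misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    if cv.n_folds > len(y):
        raise ValueError(f"n_folds={cv.n_folds} exceeds the {len(y)} samples")
    if cv.stratified and np.min(np.bincount(y)) < cv.n_folds:
        raise ValueError(
            "a class has fewer members than folds; use fewer folds"
        )
    if isinstance(features, pd.DataFrame):
        ids = list(features.index)
    else:
        ids = list(range(len(y)))

    estimator = build_estimator(spec, seed=cv.seed)
    if _has_grid(spec) and not cv.nested:
        # Non-nested variant: hyperparameters chosen once on the full data
        # (optimistically biased; kept only for protocol comparison).
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            best = _grid_search(estimator, spec, X, y, cv).best_params_
        estimator = clone(estimator).set_params(**best)
    y_pred = np.full(len(y), -1, dtype=int)
    p_stress = np.full(len(y), np.nan)
    fold_accuracies: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # sklearn 1.9 deprecation chatter from SVC(probability=True)
        warnings.simplefilter("ignore", FutureWarning)
        for train_idx, test_idx in _outer_splitter(cv).split(X, y):
            model = _fit_fold_model(estimator, spec, X[train_idx], y[train_idx], cv)
            pred = model.predict(X[test_idx])
            classes = list(model.classes_)
            proba = model.predict_proba(X[test_idx])[:, classes.index(1)]
            y_pred[test_idx] = pred
            p_stress[test_idx] = proba
            fold_accuracies.append(float(np.mean(pred == y[test_idx])))
    assert np.all(y_pred >= 0), "pooled predictions must cover every sample"
    predictions = pd.DataFrame(
        {"y_true": y, "y_pred": y_pred, "p_stress": p_stress}, index=ids
    )
    return CVResult(
        spec=spec,
        metrics=compute_metrics(y, y_pred, p_stress),
        confusion=confusion_matrix(y, y_pred),
        fold_accuracies=fold_accuracies,
        predictions=predictions,
    )


def compare_feature_sets(
    features: pd.DataFrame,
    labels: np.ndarray,
    subsets: Sequence[Sequence[str]],
    specs: Sequence[ClassifierSpec],
    cv: CVConfig = CVConfig(),
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVResult]]:
    """Accuracy grid over feature subsets x classifiers.

    Returns the accuracy table (rows: subsets as ``"+"``-joined names,
    columns: classifier kinds, cells: pooled accuracy in %) and the full
    per-cell :class:`CVResult` map.
    """
    if not len(subsets):
        raise ValueError("need at least one feature subset")
    if not len(specs):
        raise ValueError("need at least one classifier spec")
    table = pd.DataFrame(
        index=["+".join(s) for s in subsets],
        columns=[spec.kind for spec in specs],
        dtype=float,
    )
    results: dict[tuple[str, str], CVResult] = {}
    for subset in subsets:
        subset = list(subset)
        if not subset:
            raise ValueError("empty feature subset")
        missing = [f for f in subset if f not in features.columns]
        if missing:
            raise ValueError(f"unknown feature(s) {missing}")
        row = "+".join(subset)
        for spec in specs:
            result = cross_validate(features[subset], labels, spec, cv)
            table.loc[row, spec.kind] = result.metrics.accuracy
            results[(row, spec.kind)] = result
    return table, results
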
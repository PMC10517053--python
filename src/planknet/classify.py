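"""Community-type classification from satellite features.

Implements training with an exhaustive, stratified inner-CV grid search,
leave-one-out and spatially buffered cross-validation, micro-average ROC-AUC,
F1-based probability thresholding and permutation importance.

Standardization and hyperparameter selection are refit inside every outer
fold, so a held-out sample never influences the transform or grid choice of
its own fold.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_curve, auc as _auc
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .preprocess import haversine_km

logger = logging.getLogger(__name__)


class PlattSVC(BaseEstimator, ClassifierMixin):
    """Max-margin classifier with per-class Platt probability calibration.

    One-vs-rest decision values are computed out-of-fold with a stratified
    inner split (in-sample when classes are too small to fold), a logistic
    sigmoid is fitted per class, and the per-class sigmoids are normalized
    to sum to 1.
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear",
                 calibration_folds: int = 5, random_state: int = 0):
        self.C = C
        self.kernel = kernel
        self.calibration_folds = calibration_folds
        self.random_state = random_state

    def _decision_matrix(self, svc, X):
        d = svc.decision_function(X)
        if d.ndim == 1:  # binary: one margin column per class
            d = np.column_stack([-d, d])
        return d

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self._svc = SVC(
            C=self.C, kernel=self.kernel, decision_function_shape="ovr",
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self._svc.classes_

        _, counts = np.unique(y, return_counts=True)
        folds = int(min(self.calibration_folds, counts.min()))
        if folds >= 2:
            # in-sample values as fallback for fold/class gaps, then overwrite
            decision = self._decision_matrix(self._svc, X)
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=self.random_state)
            for tr, te in skf.split(X, y):
                fold_svc = SVC(
                    C=self.C, kernel=self.kernel, decision_function_shape="ovr",
                    random_state=self.random_state,
                ).fit(X[tr], y[tr])
                raw = self._decision_matrix(fold_svc, X[te])
                cols = np.searchsorted(self.classes_, fold_svc.classes_)
                decision[np.ix_(te, cols)] = raw
        else:  # too few members to fold: calibrate in-sample
            decision = self._decision_matrix(self._svc, X)

        self._calibrators = []
        for k, cls in enumerate(self.classes_):
            lr = LogisticRegression()
            lr.fit(decision[:, [k]], (y == cls).astype(int))
            self._calibrators.append(lr)
        return self

    def predict_proba(self, X):
        decision = self._decision_matrix(self._svc, np.asarray(X, dtype=float))
        scores = np.column_stack(
            [lr.predict_proba(decision[:, [k]])[:, 1]
             for k, lr in enumerate(self._calibrators)]
        )
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

#: the 17 satellite-derived parameters, in canonical column order
SATELLITE_FEATURES = [
    "rrs_412", "rrs_443", "rrs_469", "rrs_488", "rrs_531",
    "rrs_547", "rrs_555", "rrs_645", "rrs_667", "rrs_678",
    "chl_a", "kd_490", "poc", "pic", "par", "nflh", "sst",
]

#: seven non-reflectance environmental parameters
ENV_FEATURES = ["chl_a", "kd_490", "poc", "pic", "par", "nflh", "sst"]

POSITION_FEATURES = ["latitude", "sin_lon", "cos_lon"]

FEATURE_SETS = {
    "all17": SATELLITE_FEATURES,
    "env7": ENV_FEATURES,
    "sst": ["sst"],
    "chl": ["chl_a"],
    "sst_chl": ["sst", "chl_a"],
    "position": POSITION_FEATURES,
}

DEFAULT_GRIDS = {
    "svm": [{"C": c, "kernel": "linear"} for c in (0.01, 0.1, 1.0, 10.0, 100.0)],
    "knn": [{"n_neighbors": k} for k in (1, 3, 5, 7, 9)],
    "nb": [{}],
}

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


def encode_position(lat: float, lon: float) -> tuple[float, float, float]:
    """(latitude, sin(longitude), cos(longitude)); longitude is circular so
    -180 and 180 encode identically."""
    rad = np.radians(lon)
    return float(lat), float(np.sin(rad)), float(np.cos(rad))


def standardize(
    features: np.ndarray, fit_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale all rows using mean and population sd learned on
    ``fit_rows`` only. Constant columns are centered and left unscaled
    (sd treated as 1) with a warning."""
    X = np.asarray(features, dtype=float)
    fit = X[np.asarray(fit_rows)]
    means = fit.mean(axis=0)
    sds = fit.std(axis=0)
    constant = sds == 0
    if constant.any():
        logger.warning(
            "standardize: %d constant columns left unscaled", int(constant.sum())
        )
        sds = np.where(constant, 1.0, sds)
    return (X - means) / sds, means, sds


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "svm":
        return PlattSVC(random_state=seed, **params)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "nb":
        return GaussianNB(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from svm/knn/nb")


@dataclass
class TrainedClassifier:
    """Fitted multiclass model with its standardization and threshold."""

    algorithm: str
    means: np.ndarray
    sds: np.ndarray
    model: object
    classes: np.ndarray
    feature_names: list[str] | None = None
    probability_threshold: float = 0.5
    best_params: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        X = (np.asarray(features, dtype=float) - self.means) / self.sds
        return self.model.predict_proba(X)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(features), axis=1)]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "algorithm": self.algorithm,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "classes": np.asarray(self.classes).tolist(),
            "feature_names": self.feature_names,
            "probability_threshold": self.probability_threshold,
            "best_params": self.best_params,
        }
        if hasattr(self.model, "coef_"):
            manifest["coef"] = np.asarray(self.model.coef_).tolist()
            manifest["intercept"] = np.asarray(self.model.intercept_).tolist()
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(directory / "model.pkl", "wb") as fh:
            pickle.dump(self.model, fh)

    @classmethod
    def load(cls, directory) -> "TrainedClassifier":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with open(directory / "model.pkl", "rb") as fh:
            model = pickle.load(fh)
        return cls(
            algorithm=manifest["algorithm"],
            means=np.asarray(manifest["means"]),
            sds=np.asarray(manifest["sds"]),
            model=model,
            classes=np.asarray(manifest["classes"]),
            feature_names=manifest["feature_names"],
            probability_threshold=manifest["probability_threshold"],
            best_params=manifest["best_params"],
        )


def _search_estimator(algorithm: str, params: dict, seed: int):
    # class predictions only, so the svm skips probability calibration here
    if algorithm == "svm":
        return SVC(decision_function_shape="ovr", random_state=seed, **params)
    return _make_estimator(algorithm, params, seed)


def _grid_search(X, y, algorithm, hyper_grid, inner_folds, seed):
    """Exhaustive accuracy-maximizing grid search with stratified folds.

    Returns the winning parameter dict. Ties go to the earlier grid entry.
    If the smallest class cannot support 2 folds the first setting is used.
    """
    if len(hyper_grid) == 1:
        return hyper_grid[0]
    _, counts = np.unique(y, return_counts=True)
    folds = int(min(inner_folds, counts.min()))
    if folds < 2:
        return hyper_grid[0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_params, best_acc = hyper_grid[0], -1.0
    for params in hyper_grid:
        correct = 0
        for tr, te in splits:
            est = _search_estimator(algorithm, params, seed)
            est.fit(X[tr], y[tr])
            correct += int((est.predict(X[te]) == y[te]).sum())
        acc = correct / len(y)
        if acc > best_acc:
            best_params, best_acc = params, acc
    return best_params


def train(
    features: np.ndarray,
    labels: np.ndarray,
    algorithm: str = "svm",
    hyper_grid: list[dict] | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TrainedClassifier:
    """Standardize, grid-search hyperparameters with stratified inner CV
    (selection metric: accuracy), then refit on all rows."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(f"class {thin[0]!r} has fewer than 2 members")
    if hyper_grid is None:
        hyper_grid = DEFAULT_GRIDS[algorithm]
    Xs, means, sds = standardize(X, np.arange(len(X)))
    best = _grid_search(Xs, y, algorithm, hyper_grid, inner_folds, seed)
    model = _make_estimator(algorithm, best, seed)
    model.fit(Xs, y)
    return TrainedClassifier(
        algorithm=algorithm,
        means=means,
        sds=sds,
        model=model,
        classes=model.classes_,
        feature_names=feature_names,
        best_params=best,
    )


@dataclass
class CvResult:
    """Per-sample cross-validation predictions and summary metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray
    prob: np.ndarray  # (n_evaluated, n_classes)
    classes: np.ndarray
    accuracy: float
    micro_auc: float
    confusion: np.ndarray  # (K, K) counts, rows = true
    evaluated: np.ndarray  # indices of evaluated samples
    skipped: np.ndarray  # indices skipped (empty training set)

    def summary(self) -> dict:
        return {
            "n_evaluated": int(len(self.evaluated)),
            "n_skipped": int(len(self.skipped)),
            "accuracy": float(self.accuracy),
            "micro_auc": float(self.micro_auc),
        }

    def per_sample_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.prob, columns=[f"prob_{c}" for c in self.classes]
        )
        frame.insert(0, "index", self.evaluated)
        frame.insert(1, "y_true", self.y_true)
        frame.insert(2, "y_pred", self.y_pred)
        return frame


def micro_roc_auc(prob_matrix: np.ndarray, labels: np.ndarray, classes=None) -> float:
    """Micro-average one-vs-rest ROC-AUC: pool the per-class indicator and
    probability columns and take the trapezoidal AUC of the pooled ROC."""
    prob = np.asarray(prob_matrix, dtype=float)
    y = np.asarray(labels)
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray(classes)
    if len(np.unique(y)) < 2:
        raise ValueError("micro ROC-AUC undefined with a single class present")
    indicator = (y[:, None] == classes[None, :]).astype(int)
    fpr, tpr, _ = roc_curve(indicator.ravel(), prob.ravel())
    return float(_auc(fpr, tpr))


def _predict_fold(X, y, train_idx, test_idx, algorithm, hyper_grid, inner_folds, seed, classes):
    """Fit on train_idx (standardize + grid search inside), return the
    probability row(s) for test_idx aligned to the global class order."""
    Xs, means, sds = standardize(X, train_idx)
    ytr = y[train_idx]
    present = np.unique(ytr)
    if len(present) == 1:
        logger.warning("fold has a single training class %r", present[0])
        prob = np.zeros((len(test_idx), len(classes)))
        prob[:, np.flatnonzero(classes == present[0])[0]] = 1.0
        return prob
    if hyper_grid is None:
        hyper_grid = DEFAULT_GRIDS[algorithm]
    best = _grid_search(Xs[train_idx], ytr, algorithm, hyper_grid, inner_folds, seed)
    model = _make_estimator(algorithm, best, seed)
    model.fit(Xs[train_idx], ytr)
    raw = model.predict_proba(Xs[test_idx])
    prob = np.zeros((len(test_idx), len(classes)))
    for j, c in enumerate(model.classes_):
        prob[:, np.flatnonzero(classes == c)[0]] = raw[:, j]
    return prob


def _assemble_cv(y, classes, prob_rows, evaluated, skipped) -> CvResult:
    evaluated = np.asarray(evaluated, dtype=int)
    skipped = np.asarray(skipped, dtype=int)
    prob = np.vstack(prob_rows) if prob_rows else np.zeros((0, len(classes)))
    y_true = y[evaluated]
    y_pred = classes[np.argmax(prob, axis=1)] if len(prob) else np.array([])
    acc = float(np.mean(y_pred == y_true)) if len(y_true) else float("nan")
    try:
        auc_value = micro_roc_auc(prob, y_true, classes)
    except ValueError:
        auc_value = float("nan")
    if len(y_true):
        conf = confusion_matrix(y_true, y_pred, labels=classes)
    else:
        conf = np.zeros((len(classes), len(classes)), dtype=int)
    return CvResult(
        y_true=y_true, y_pred=y_pred, prob=prob, classes=classes,
        accuracy=acc, micro_auc=auc_value, confusion=conf,
        evaluated=evaluated, skipped=skipped,
    )


def loo_cv(
    features: np.ndarray,
    labels: np.ndarray,
    algorithm: str = "svm",
    hyper_grid: list[dict] | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> CvResult:
    """Leave-one-out cross-validation with nested grid search per fold."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    classes = np.unique(y)
    prob_rows = []
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        prob_rows.append(
            _predict_fold(X, y, train_idx, np.array([i]), algorithm,
                          hyper_grid, inner_folds, seed, classes)
        )
    return _assemble_cv(y, classes, prob_rows, np.arange(n), [])


def buffered_training_indices(coords: np.ndarray, test_index: int, radius_km: float) -> np.ndarray:
    """Indices usable for training when ``test_index`` is held out: the test
    sample itself and every sample strictly within ``radius_km`` (haversine)
    of it are excluded."""
    coords = np.asarray(coords, dtype=float)
    dists = haversine_km(np.broadcast_to(coords[test_index], coords.shape), coords)
    mask = dists >= radius_km
    mask[test_index] = False
    return np.flatnonzero(mask)


def buffered_cv(
    features: np.ndarray,
    labels: np.ndarray,
    coords: np.ndarray,
    radius_km: float,
    algorithm: str = "svm",
    hyper_grid: list[dict] | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> CvResult:
    """Leave-one-out CV that additionally excludes training samples strictly
    within ``radius_km`` (haversine) of the test sample. Folds with an empty
    training set are skipped and reported; radius 0 reproduces plain LOO."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(y), 2):
        raise ValueError("coords must be (n, 2) latitude/longitude pairs")
    n = len(y)
    classes = np.unique(y)
    prob_rows, evaluated, skipped = [], [], []
    for i in range(n):
        train_idx = buffered_training_indices(coords, i, radius_km)
        if len(train_idx) == 0:
            logger.warning("buffered_cv: sample %d has empty training set; skipped", i)
            skipped.append(i)
            continue
        prob_rows.append(
            _predict_fold(X, y, train_idx, np.array([i]), algorithm,
                          hyper_grid, inner_folds, seed, classes)
        )
        evaluated.append(i)
    return _assemble_cv(y, classes, prob_rows, evaluated, skipped)


def micro_f1(prob: np.ndarray, labels: np.ndarray, classes: np.ndarray, threshold: float) -> float:
    """Micro-averaged one-vs-rest F1 of 'predict every class whose
    probability is >= threshold'."""
    indicator = (np.asarray(labels)[:, None] == np.asarray(classes)[None, :])
    predicted = np.asarray(prob) >= threshold
    tp = int((predicted & indicator).sum())
    fp = int((predicted & ~indicator).sum())
    fn = int((~predicted & indicator).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(
    cv_probs: np.ndarray,
    labels: np.ndarray,
    classes: np.ndarray,
    grid=DEFAULT_THRESHOLD_GRID,
) -> float:
    """Grid value maximizing micro-averaged F1; ties break to the smallest
    threshold."""
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid must be nonempty")
    best_t, best_f1 = grid[0], -1.0
    for t in grid:
        f1 = micro_f1(cv_probs, labels, classes, t)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t


def permutation_importance(
    model: TrainedClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean decrease in micro ROC-AUC when one feature column is shuffled.

    Returns a mapping from feature name (or ``f{i}``) to mean AUC drop over
    ``n_repeats`` shuffles.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    baseline = micro_roc_auc(model.predict_proba(X), y, model.classes)
    names = model.feature_names or [f"f{i}" for i in range(X.shape[1])]
    out = {}
    for j, name in enumerate(names):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            drops.append(baseline - micro_roc_auc(model.predict_proba(Xp), y, model.classes))
        out[name] = float(np.mean(drops))
    return out
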
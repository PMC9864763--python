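"""QSAR model training: five algorithm families, Bayesian tuning, Y-scrambling.

`QSARRegressor` and `QSARClassifier` are scikit-learn style estimators that
wrap one of five algorithm families (random forest, SVM, k-NN, gradient
boosted trees, neural net) and tune its hyperparameters with sequential
model-based optimization maximizing the mean five-fold cross-validation
score (R2 for regression, balanced accuracy for classification).  The final
model is refit on the full training set with the best configuration.

Internal validation statistics follow QSAR convention: R2/RMSE on the
training fit, and Q2 = 1 - PRESS/TSS over pooled out-of-fold predictions.
Quality gates (R2 > 0.6, Q2 > 0.5) are computed as flags, never asserted.
Y-scrambling refits the tuned configuration on label permutations to show
the true model's statistic is not a chance artifact.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted

from .datasets import rebalance_train
from .optimize import Categorical, Integer, Real, bayes_search

__all__ = [
    "Algorithm",
    "default_search_space",
    "QSARRegressor",
    "QSARClassifier",
    "RegressionCVStats",
    "ClassificationCVStats",
    "ScrambleResult",
    "y_scramble",
    "save_model",
    "load_model",
]


class Algorithm(str, enum.Enum):
    RANDOM_FOREST = "random_forest"
    SVM = "svm"
    KNN = "knn"
    GRADIENT_BOOSTED_TREES = "gradient_boosted_trees"
    NEURAL_NET = "neural_net"


def default_search_space(algorithm: Algorithm | str) -> dict:
    """Conventional, user-overridable hyperparameter ranges per family."""
    algorithm = Algorithm(algorithm)
    if algorithm is Algorithm.RANDOM_FOREST:
        return {"n_estimators": Integer(100, 1000), "max_depth": Integer(2, 30)}
    if algorithm is Algorithm.SVM:
        return {"C": Real(1e-3, 1e3, log=True), "gamma": Real(1e-3, 1e3, log=True)}
    if algorithm is Algorithm.KNN:
        return {
            "n_neighbors": Integer(1, 30),
            "weights": Categorical(("uniform", "distance")),
        }
    if algorithm is Algorithm.GRADIENT_BOOSTED_TREES:
        return {
            "learning_rate": Real(1e-3, 0.3, log=True),
            "max_depth": Integer(2, 12),
            "n_estimators": Integer(100, 500),
        }
    if algorithm is Algorithm.NEURAL_NET:
        return {
            "n_layers": Integer(1, 4),
            "units": Integer(32, 512, log=True),
            "alpha": Real(1e-6, 1e-2, log=True),
        }
    raise ValueError(algorithm)


def _make_estimator(algorithm: Algorithm, task: str, params: dict, seed: int):
    params = dict(params)
    if algorithm is Algorithm.RANDOM_FOREST:
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(random_state=seed, n_jobs=1, **params)
    if algorithm is Algorithm.SVM:
        if task == "regression":
            return SVR(**params)
        return SVC(probability=True, random_state=seed, **params)
    if algorithm is Algorithm.KNN:
        cls = KNeighborsRegressor if task == "regression" else KNeighborsClassifier
        return cls(**params)
    if algorithm is Algorithm.GRADIENT_BOOSTED_TREES:
        from xgboost import XGBClassifier, XGBRegressor

        cls = XGBRegressor if task == "regression" else XGBClassifier
        return cls(random_state=seed, n_jobs=1, tree_method="hist",
                   verbosity=0, **params)
    if algorithm is Algorithm.NEURAL_NET:
        layers = tuple([params.pop("units")] * params.pop("n_layers"))
        cls = MLPRegressor if task == "regression" else MLPClassifier
        return cls(hidden_layer_sizes=layers, random_state=seed, max_iter=500,
                   **params)
    raise ValueError(algorithm)


@dataclass
class RegressionCVStats:
    R2_train: float
    Q2: float
    RMSE_int: float
    RMSE_CV: float

    def gates(self) -> dict[str, bool]:
        """Internal-validation quality gates (computed, never hard-coded)."""
        return {"R2_gt_0.6": self.R2_train > 0.6, "Q2_gt_0.5": self.Q2 > 0.5}


@dataclass
class ClassificationCVStats:
    fold_balanced_accuracy: list[float]
    fold_mcc: list[float]

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.fold_balanced_accuracy))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.fold_mcc))


@dataclass
class ScrambleResult:
    """Statistics of models refit on permuted labels vs. the true model."""

    scrambled_stats: list[float]
    true_stat: float

    @property
    def mean_scrambled(self) -> float:
        return float(np.mean(self.scrambled_stats))


def _check_labels(y):
    y = np.asarray(y)
    if y.dtype.kind == "f" and not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    return y


def _oof_predictions(estimator, X, y, cv, seed):
    """Pooled out-of-fold predictions for Q2 / RMSE_CV."""
    pred = np.empty(len(y), dtype=float)
    splitter = KFold(cv, shuffle=True, random_state=seed)
    for tr, va in splitter.split(X):
        est = clone(estimator)
        est.fit(X[tr], y[tr])
        pred[va] = est.predict(X[va])
    return pred


def _q2_from_oof(y, oof):
    press = float(np.sum((y - oof) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        # constant labels: Q2 undefined
        return float("nan")
    return 1.0 - press / tss


class QSARRegressor(BaseEstimator, RegressorMixin):
    """Tuned regression model for pIC50 prediction.

    Parameters mirror the model specification: algorithm family, search
    space (defaults per family), evaluation budget, CV folds, and seed.

    Fitted attributes: ``best_params_``, ``estimator_``, ``cv_stats_``
    (:class:`RegressionCVStats`), ``search_history_``.
    """

    def __init__(self, algorithm="random_forest", search_space=None, budget=20,
                 cv=5, random_state=0):
        self.algorithm = algorithm
        self.search_space = search_space
        self.budget = budget
        self.cv = cv
        self.random_state = random_state

    def _space(self):
        return self.search_space or default_search_space(self.algorithm)

    def fit(self, X, y):
        X = np.asarray(X)
        y = _check_labels(y).astype(float)
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        algorithm = Algorithm(self.algorithm)
        seed = self.random_state

        def objective(params):
            est = _make_estimator(algorithm, "regression", params, seed)
            oof = _oof_predictions(est, X, y, self.cv, seed)
            q2 = _q2_from_oof(y, oof)
            return q2 if np.isfinite(q2) else -1.0

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, history = bayes_search(objective, self._space(), self.budget, seed)
            self.best_params_ = best
            self.search_history_ = history
            self.estimator_ = _make_estimator(algorithm, "regression", best, seed)
            self.estimator_.fit(X, y)
            oof = _oof_predictions(self.estimator_, X, y, self.cv, seed)
        fit_pred = self.estimator_.predict(X)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.cv_stats_ = RegressionCVStats(
            R2_train=(1.0 - float(np.sum((y - fit_pred) ** 2)) / tss
                      if tss > 0 else float("nan")),
            Q2=_q2_from_oof(y, oof),
            RMSE_int=float(np.sqrt(np.mean((y - fit_pred) ** 2))),
            RMSE_CV=float(np.sqrt(np.mean((y - oof) ** 2))),
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.estimator_.predict(X)


class QSARClassifier(BaseEstimator, ClassifierMixin):
    """Tuned binary or multiclass model with optional in-fold SMOTE.

    The tuning objective is mean five-fold cross-validated balanced
    accuracy.  When ``rebalance=True``, SMOTE is applied inside each
    training fold only (validation folds are never rebalanced), and to the
    full training set for the final refit.
    """

    def __init__(self, algorithm="random_forest", search_space=None, budget=20,
                 cv=5, rebalance=False, random_state=0):
        self.algorithm = algorithm
        self.search_space = search_space
        self.budget = budget
        self.cv = cv
        self.rebalance = rebalance
        self.random_state = random_state

    def _space(self):
        return self.search_space or default_search_space(self.algorithm)

    def _cv_scores(self, est, X, y, seed):
        splitter = StratifiedKFold(self.cv, shuffle=True, random_state=seed)
        bas, mccs = [], []
        for tr, va in splitter.split(X, y):
            Xtr, ytr = X[tr], y[tr]
            if self.rebalance:
                Xtr, ytr, _ = rebalance_train(Xtr, ytr, seed=seed)
            e = clone(est)
            e.fit(Xtr, ytr)
            pred = e.predict(X[va])
            bas.append(balanced_accuracy_score(y[va], pred))
            mccs.append(matthews_corrcoef(y[va], pred))
        return bas, mccs

    def fit(self, X, y):
        X = np.asarray(X)
        y = _check_labels(y)
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        algorithm = Algorithm(self.algorithm)
        seed = self.random_state
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        y_enc = self._encoder.transform(y)

        def objective(params):
            est = _make_estimator(algorithm, "classification", params, seed)
            bas, _ = self._cv_scores(est, X, y_enc, seed)
            return float(np.mean(bas))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, history = bayes_search(objective, self._space(), self.budget, seed)
            self.best_params_ = best
            self.search_history_ = history
            est = _make_estimator(algorithm, "classification", best, seed)
            bas, mccs = self._cv_scores(est, X, y_enc, seed)
            self.cv_stats_ = ClassificationCVStats(
                fold_balanced_accuracy=[float(b) for b in bas],
                fold_mcc=[float(m) for m in mccs],
            )
            Xf, yf = X, y_enc
            if self.rebalance:
                Xf, yf, _ = rebalance_train(X, y_enc, seed=seed)
            self.estimator_ = est.fit(Xf, yf)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def y_scramble(model, X, y, n_reps: int = 100, random_state: int = 0) -> ScrambleResult:
    """Refit the tuned configuration on permuted labels ``n_reps`` times.

    Each repetition permutes the labels independently and recomputes the
    model's headline cross-validated statistic (Q2 for regression, mean CV
    balanced accuracy for classification) with the same hyperparameters as
    the fitted model.  A sound model's true statistic should sit far above
    the scrambled distribution, which for Q2 hovers at or below zero.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    check_is_fitted(model, "estimator_")
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(random_state)
    is_regression = isinstance(model, QSARRegressor)
    algorithm = Algorithm(model.algorithm)
    stats = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            y_perm = rng.permutation(y)
            seed = int(rng.integers(2**31))
            if is_regression:
                est = _make_estimator(algorithm, "regression", model.best_params_, seed)
                oof = _oof_predictions(est, X, y_perm.astype(float), model.cv, seed)
                stats.append(_q2_from_oof(y_perm.astype(float), oof))
            else:
                est = _make_estimator(algorithm, "classification",
                                      model.best_params_, seed)
                y_enc = LabelEncoder().fit_transform(y_perm)
                bas, _ = model._cv_scores(est, X, y_enc, seed)
                stats.append(float(np.mean(bas)))
    true_stat = (model.cv_stats_.Q2 if is_regression
                 else model.cv_stats_.mean_balanced_accuracy)
    return ScrambleResult(scrambled_stats=[float(s) for s in stats],
                          true_stat=float(true_stat))


def save_model(model, directory: str | Path) -> None:
    """Persist a fitted model as a schema-versioned bundle directory."""
    check_is_fitted(model, "estimator_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, directory / "model.bin")
    spec = {
        "schema_version": 1,
        "class": type(model).__name__,
        "algorithm": str(Algorithm(model.algorithm).value),
        "budget": model.budget,
        "cv": model.cv,
        "random_state": model.random_state,
        "best_params": model.best_params_,
    }
    (directory / "spec.json").write_text(json.dumps(spec, indent=2, default=str))
    stats = model.cv_stats_
    (directory / "cv_stats.json").write_text(
        json.dumps(asdict(stats), indent=2, default=float)
    )


def load_model(directory: str | Path):
    return joblib.load(Path(directory) / "model.bin")
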
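"""Thin uniform layer over scikit-learn classifiers and regressors.

Seven algorithm families are exposed under short ids, each usable as a binary
classifier (link / nonlink) or a weight regressor, with hyperparameters fixed
to the values the analyses were run with:

* KNN — k-nearest neighbors, ``n_neighbors=5, leaf_size=30``
* DT  — decision tree, library defaults
* RF  — random forest, ``n_estimators=200``, Gini impurity (classification)
* MLP — multilayer perceptron, one hidden layer of 100, ``tol=1e-6``,
  ``max_iter=20`` (kept deliberately small; convergence warnings are expected
  and silenced — override via hyperparameters if convergence matters)
* GB  — gradient boosting, ``n_estimators=100, max_depth=7``
* ADA — AdaBoost, defaults
* NBA — Gaussian naive Bayes, classifier only

Classifier ``predict`` returns a continuous score in [0, 1] per pair (the
positive-class probability, or a min-max-scaled decision value for estimators
without ``predict_proba``) so ROC curves can be built; regressors return raw
real-valued weights, flagged (not clipped) when outside the empirical [0, 7]
range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .errors import (
    DegenerateLabels,
    FeatureLengthMismatch,
    NonFiniteFeature,
    UnknownMethod,
)
from .features import DesignMatrix

ALGORITHMS = ("KNN", "DT", "RF", "MLP", "GB", "ADA", "NBA")
#: the four classifiers/regressors used in headline analyses; DT/ADA/NBA
#: are supported but performed worse and are excluded from default reports
TOP_ALGORITHMS = ("KNN", "MLP", "RF", "GB")

_SEEDABLE = {"DT", "RF", "MLP", "GB", "ADA"}


@dataclass(frozen=True)
class PredictorConfig:
    algorithm: str = "GB"
    mode: str = "classifier"  # "classifier" | "regressor"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise UnknownMethod(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.mode not in ("classifier", "regressor"):
            raise UnknownMethod(f"mode must be 'classifier' or 'regressor', got {self.mode!r}")
        if self.algorithm == "NBA" and self.mode == "regressor":
            raise UnknownMethod("NBA (naive Bayes) supports classification only")


def _make_estimator(config: PredictorConfig):
    hp = dict(config.hyperparameters)
    alg, clf = config.algorithm, config.mode == "classifier"
    if alg in _SEEDABLE:
        hp.setdefault("random_state", config.seed)
    if alg == "KNN":
        hp.setdefault("n_neighbors", 5)
        hp.setdefault("leaf_size", 30)
        return KNeighborsClassifier(**hp) if clf else KNeighborsRegressor(**hp)
    if alg == "DT":
        return DecisionTreeClassifier(**hp) if clf else DecisionTreeRegressor(**hp)
    if alg == "RF":
        hp.setdefault("n_estimators", 200)
        if clf:
            hp.setdefault("criterion", "gini")
            return RandomForestClassifier(**hp)
        return RandomForestRegressor(**hp)
    if alg == "MLP":
        hp.setdefault("hidden_layer_sizes", (100,))
        hp.setdefault("tol", 1e-6)
        hp.setdefault("max_iter", 20)
        return MLPClassifier(**hp) if clf else MLPRegressor(**hp)
    if alg == "GB":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_depth", 7)
        return GradientBoostingClassifier(**hp) if clf else GradientBoostingRegressor(**hp)
    if alg == "ADA":
        return AdaBoostClassifier(**hp) if clf else AdaBoostRegressor(**hp)
    return GaussianNB(**hp)


@dataclass
class TrainedPredictor:
    """A fitted estimator plus the metadata needed to validate predictions."""

    config: PredictorConfig
    estimator: Any
    n_features: int
    n_train: int
    out_of_range_flagged: bool = False


def fit(config: PredictorConfig, dm: DesignMatrix) -> TrainedPredictor:
    """Fit the configured estimator on a labeled design matrix."""
    if dm.n_pairs == 0 or dm.y is None:
        raise DegenerateLabels("training requires a non-empty labeled design matrix")
    if not np.all(np.isfinite(dm.X)):
        raise NonFiniteFeature("training features contain non-finite values")
    if config.mode == "classifier" and np.unique(dm.y).size < 2:
        raise DegenerateLabels("classifier training labels contain a single class")
    if config.algorithm == "KNN" and dm.n_pairs < int(
        config.hyperparameters.get("n_neighbors", 5)
    ):
        # tiny training sets (leave-one-out at small m): shrink k to fit
        config = PredictorConfig(
            algorithm="KNN", mode=config.mode, seed=config.seed,
            hyperparameters={**config.hyperparameters, "n_neighbors": dm.n_pairs},
        )
    est = _make_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(dm.X, dm.y)
    return TrainedPredictor(
        config=config, estimator=est, n_features=dm.X.shape[1], n_train=dm.n_pairs
    )


def predict(handle: TrainedPredictor, dm: DesignMatrix) -> np.ndarray:
    """Scores in [0, 1] (classifier) or real weights (regressor) per pair."""
    if dm.n_pairs == 0:
        return np.zeros(0)
    if dm.X.shape[1] != handle.n_features:
        raise FeatureLengthMismatch(
            f"got {dm.X.shape[1]} features, trained with {handle.n_features}"
        )
    est = handle.estimator
    if handle.config.mode == "classifier":
        if hasattr(est, "predict_proba"):
            return est.predict_proba(dm.X)[:, 1]
        raw = est.decision_function(dm.X)
        lo, hi = raw.min(), raw.max()
        return (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)
    out = est.predict(dm.X)
    if np.any((out < 0) | (out > 7)):
        handle.out_of_range_flagged = True
    return out
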
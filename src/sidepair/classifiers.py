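"""Uniform contract over the 13-classifier roster.

Backends are scikit-learn estimators.  The contract pins only what matters
to the method (the random forest uses 100 trees; scores live in [0, 1];
label = score >= 0.5, boundary inclusive); everything else is backend
defaults, recorded per fit for auditability.

Three roster names have no native scikit-learn equivalent and are served by
registered substitutes flagged ``approximate``: ``bayes_net`` (a Bayes
classifier over uniformly discretized features), ``part`` (an entropy-split
decision tree standing in for the partial-tree rule learner), and
``ripper`` (a cost-complexity-pruned tree standing in for the rule
inducer).  ``decision_tree`` is CART rather than C4.5 and is flagged too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: Roster names whose backend is a substitute for the named algorithm.
APPROXIMATE_BACKENDS = frozenset({"bayes_net", "part", "ripper", "decision_tree"})


def _build_backend(name: str, seed: int, params: dict):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **params)
    if name == "svm_poly":
        return SVC(kernel="poly", random_state=seed, **params)
    if name == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "adaboost_m1":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "bagging":
        return BaggingClassifier(random_state=seed, **params)
    if name == "bayes_net":
        n_bins = params.pop("n_bins", 5)
        return Pipeline(
            [
                ("discretize", KBinsDiscretizer(n_bins=n_bins, encode="ordinal", strategy="uniform")),
                ("nb", CategoricalNB(min_categories=n_bins, **params)),
            ]
        )
    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "part":
        return DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2, random_state=seed, **params)
    if name == "logistic":
        return LogisticRegression(max_iter=1000, **params)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=500, random_state=seed, **params)
    if name == "ripper":
        return DecisionTreeClassifier(criterion="entropy", ccp_alpha=0.01, random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}; expected one of {sorted(CLASSIFIER_NAMES)}")


CLASSIFIER_NAMES = frozenset(
    {
        "random_forest",
        "svm_poly",
        "svm_rbf",
        "adaboost_m1",
        "bagging",
        "bayes_net",
        "naive_bayes",
        "knn",
        "decision_tree",
        "part",
        "logistic",
        "mlp",
        "ripper",
    }
)


@dataclass(frozen=True)
class ClassifierSpec:
    name: str = "random_forest"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; expected one of {sorted(CLASSIFIER_NAMES)}")

    @property
    def approximate(self) -> bool:
        return self.name in APPROXIMATE_BACKENDS


@dataclass
class FittedModel:
    """Trained backend plus the spec that produced it.

    Scores any matrix of the training feature width and refuses others.
    Backends without probability output are min–max calibrated to [0, 1]
    on their training scores.
    """

    spec: ClassifierSpec
    backend: Any
    n_features: int
    calibration: tuple[float, float] | None  # (min, max) of training decision scores

    def backend_params(self) -> dict:
        """Every backend hyperparameter, for the run log."""
        return {k: repr(v) for k, v in self.backend.get_params(deep=True).items()}


def fit(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have matching first dimensions")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if X.shape[1] < 1:
        raise ValueError("feature width must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    backend = _build_backend(spec.name, spec.seed, dict(spec.params))
    backend.fit(X, y)
    calibration = None
    if not hasattr(backend, "predict_proba"):
        train_scores = backend.decision_function(X)
        calibration = (float(train_scores.min()), float(train_scores.max()))
    return FittedModel(spec=spec, backend=backend, n_features=X.shape[1], calibration=calibration)


def predict_scores(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-row scores in [0, 1] (probability of the positive class, or the
    calibrated decision value)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else 'n/a'} does not match "
            f"training width {model.n_features}"
        )
    if model.calibration is None:
        classes = list(model.backend.classes_)
        scores = model.backend.predict_proba(X)[:, classes.index(1)]
    else:
        lo, hi = model.calibration
        raw = model.backend.decision_function(X)
        if hi > lo:
            scores = (raw - lo) / (hi - lo)
        else:
            scores = np.full(len(raw), 0.5)
    return np.clip(scores, 0.0, 1.0)


def labels_from_scores(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Thresholded labels; the boundary score counts as positive."""
    return (np.asarray(scores) >= threshold).astype(int)


def predict_labels(model: FittedModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return labels_from_scores(predict_scores(model, X), threshold)


def save_model(model: FittedModel, path, feature_names: list[str] | None = None) -> None:
    """Self-describing archive: spec, seed, feature layout, backend payload."""
    joblib.dump(
        {
            "spec": model.spec,
            "n_features": model.n_features,
            "feature_names": feature_names,
            "calibration": model.calibration,
            "backend": model.backend,
        },
        path,
    )


def load_model(path) -> FittedModel:
    payload = joblib.load(path)
    return FittedModel(
        spec=payload["spec"],
        backend=payload["backend"],
        n_features=payload["n_features"],
        calibration=payload["calibration"],
    )
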
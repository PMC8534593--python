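"""Classical three-class tumor classification on 4-feature vectors.

Four standard classifiers — decision tree (dt), k-nearest neighbors (knn),
support vector machine (svm) and Gaussian naive Bayes (nb) — are trained on
the per-image feature vectors and scored with confusion matrices.  Features
are z-scored with training-set statistics before the scale-sensitive
classifiers (knn, svm).  scikit-learn provides the estimators; this module
fixes hyperparameter defaults, seeding and the confusion-matrix contract.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

KINDS = ("dt", "knn", "svm", "nb")
_SCALED_KINDS = {"knn", "svm"}


@dataclasses.dataclass
class ClassifierSpec:
    """Which classifier to build and with what hyperparameters.

    Defaults (the conventional choices, surfaced explicitly): knn k=5,
    svm RBF kernel with C=1, dt unlimited depth with seeded tie-breaking,
    Gaussian nb.
    """

    kind: str
    hyperparameters: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


@dataclasses.dataclass
class ConfusionMatrix:
    """Integer confusion counts; rows = true class, cols = predicted."""

    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


@dataclasses.dataclass
class FittedClassifier:
    spec: ClassifierSpec
    estimator: Any
    scaler: StandardScaler | None
    classes: np.ndarray

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X) if self.scaler is not None else X


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp)
    if spec.kind == "svm":
        return SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0),
                   random_state=spec.seed, **hp)
    if spec.kind == "dt":
        return DecisionTreeClassifier(max_depth=hp.pop("depth", None),
                                      random_state=spec.seed, **hp)
    return GaussianNB(**hp)


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (n_samples, n_features) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X


def train(spec: ClassifierSpec, features: np.ndarray, labels: np.ndarray) -> FittedClassifier:
    """Fit one classifier; deterministic given ``spec.seed``."""
    X = _check_features(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if len(X) != len(y):
        raise ValueError("features and labels disagree in length")
    scaler = None
    if spec.kind in _SCALED_KINDS:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = _build_estimator(spec).fit(X, y)
    return FittedClassifier(spec=spec, estimator=est, scaler=scaler,
                            classes=np.asarray(est.classes_))


def predict(model: FittedClassifier, features: np.ndarray) -> np.ndarray:
    X = _check_features(features)
    return model.estimator.predict(model._transform(X))


def predict_proba(model: FittedClassifier, features: np.ndarray) -> np.ndarray:
    """Per-class scores aligned with ``model.classes``.

    Probabilities where the estimator provides them; for the margin-based
    SVM, softmax-normalized one-vs-rest decision values (a monotone score,
    which is all ROC analysis needs).
    """
    X = model._transform(_check_features(features))
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)
    margins = est.decision_function(X)
    if margins.ndim == 1:  # binary: one margin column
        margins = np.column_stack([-margins, margins])
    e = np.exp(margins - margins.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def evaluate(model: FittedClassifier, features: np.ndarray,
             labels: np.ndarray) -> ConfusionMatrix:
    """Confusion matrix of the model on a labeled feature table."""
    y_true = np.asarray(labels)
    y_pred = predict(model, features)
    classes = np.unique(np.concatenate([model.classes, y_true]))
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    return ConfusionMatrix(counts=counts, classes=classes)
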
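"""Weight-balanced multiclass substrate classifiers over encoded signatures.

Substrate datasets are heavily imbalanced (a handful of monomers such as
phenylalanine dominate), which biases classifiers toward frequent labels.
Weight balancing rescales the loss of each training example by the inverse
of its class count, ``w_t = 1 / b_t`` where ``b_t`` is the number of
training points with label ``y_t``, so every class contributes exactly 1 to
the total loss regardless of its frequency.

Backends are standard scikit-learn estimators behind a uniform train /
predict / persist surface; predictions are full probability vectors over the
label vocabulary so downstream consumers can rank candidate substrates.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy.special import softmax
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import (
    LogisticRegression,
    RidgeClassifier,
    RidgeClassifierCV,
)
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_FORMAT_VERSION = 1

#: Backends that cannot weight individual samples in their fit criterion.
_NO_SAMPLE_WEIGHT = {"knn", "mlp"}

#: Backends whose raw scores are decision values, not calibrated
#: probabilities; their outputs pass through a softmax and should be read as
#: rankings rather than probabilities.
SOFTMAX_BACKENDS = {"ridge", "ridge_cv"}

BACKENDS = (
    "extra_trees",
    "random_forest",
    "logistic_regression",
    "decision_tree",
    "svm",
    "knn",
    "mlp",
    "bernoulli_nb",
    "gaussian_nb",
    "ridge",
    "ridge_cv",
)


def compute_sample_weights(labels: Sequence[str]) -> np.ndarray:
    """Inverse-class-frequency weights: ``w_t = 1 / b_t``.

    For every class ``c``, the weights of its examples sum to exactly 1, so
    all classes contribute equally to a weighted loss.
    """
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    counts = Counter(labels)
    return np.array([1.0 / counts[y] for y in labels])


def _make_estimator(backend: str, seed: int, hyperparams: Mapping | None):
    hp = dict(hyperparams or {})
    if backend == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=hp.pop("n_estimators", 500), random_state=seed, **hp
        )
    if backend == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500), random_state=seed, **hp
        )
    if backend == "logistic_regression":
        return LogisticRegression(max_iter=hp.pop("max_iter", 2000), **hp)
    if backend == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if backend == "svm":
        # RBF kernel with Platt-style probability calibration.
        return SVC(
            kernel=hp.pop("kernel", "rbf"),
            probability=True,
            random_state=seed,
            **hp,
        )
    if backend == "knn":
        return KNeighborsClassifier(**hp)
    if backend == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (128,)),
            max_iter=hp.pop("max_iter", 500),
            random_state=seed,
            **hp,
        )
    if backend == "bernoulli_nb":
        return BernoulliNB(**hp)
    if backend == "gaussian_nb":
        return GaussianNB(**hp)
    if backend == "ridge":
        return RidgeClassifier(**hp)
    if backend == "ridge_cv":
        return RidgeClassifierCV(**hp)
    if backend == "gnn":
        raise ValueError("backend 'gnn' is unsupported")
    raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")


@dataclass
class ClassifierModel:
    """A fitted substrate classifier plus the metadata needed to reuse it."""

    backend: str
    scheme: str
    label_vocabulary: tuple[str, ...]
    weight_balanced: bool
    seed: int
    estimator: object
    n_features: int
    positions_hash: str | None = None

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Probability matrix aligned to ``label_vocabulary`` columns."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model's "
                f"{self.scheme!r} encoding ({self.n_features})"
            )
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
        else:
            scores = est.decision_function(X)
            if scores.ndim == 1:  # binary: one column of margins
                scores = np.column_stack([-scores, scores])
            proba = softmax(scores, axis=1)
        # est.classes_ is sorted, as is the vocabulary; map defensively anyway
        order = [list(est.classes_).index(lbl) for lbl in self.label_vocabulary]
        proba = proba[:, order]
        return proba / proba.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SubstratePrediction:
    """Ranked substrate candidates for one signature."""

    ranked: tuple[tuple[str, float], ...]

    @property
    def top(self) -> str:
        return self.ranked[0][0]

    def __post_init__(self) -> None:
        total = sum(score for _, score in self.ranked)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"scores sum to {total}, expected 1")


def train(
    X: np.ndarray,
    labels: Sequence[str],
    backend: str = "extra_trees",
    weight_balanced: bool = False,
    seed: int = 0,
    scheme: str = "onehot",
    hyperparams: Mapping | None = None,
    positions_hash: str | None = None,
) -> ClassifierModel:
    """Fit a substrate classifier on encoded signatures.

    When ``weight_balanced`` is set, per-example weights from
    :func:`compute_sample_weights` rescale the backend's loss; backends that
    cannot weight samples (knn, mlp) reject the flag.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ValueError("feature matrix and labels disagree in length")
    vocab = tuple(sorted(set(labels)))
    if len(vocab) < 2:
        raise ValueError("training set must contain at least 2 distinct labels")

    estimator = _make_estimator(backend, seed, hyperparams)
    if weight_balanced:
        if backend in _NO_SAMPLE_WEIGHT:
            raise ValueError(
                f"backend {backend!r} does not support sample weights; "
                "cannot train with weight_balanced=True"
            )
        estimator.fit(X, labels, sample_weight=compute_sample_weights(labels))
    else:
        estimator.fit(X, labels)

    return ClassifierModel(
        backend=backend,
        scheme=scheme,
        label_vocabulary=vocab,
        weight_balanced=weight_balanced,
        seed=seed,
        estimator=estimator,
        n_features=X.shape[1],
        positions_hash=positions_hash,
    )


def predict(model: ClassifierModel, features: np.ndarray) -> SubstratePrediction:
    """Rank all substrates for one encoded signature.

    Scores are the model's class probabilities (softmax-normalized decision
    scores for backends without native probabilities). Ties are broken
    alphabetically on the label token.
    """
    proba = model.predict_proba_matrix(np.atleast_2d(features))[0]
    # sort by descending score, then label; vocabulary is already sorted so
    # a stable sort on -score keeps alphabetical order within ties
    order = sorted(range(len(proba)), key=lambda i: (-proba[i], model.label_vocabulary[i]))
    ranked = tuple((model.label_vocabulary[i], float(proba[i])) for i in order)
    return SubstratePrediction(ranked)


def predict_batch(model: ClassifierModel, X: np.ndarray) -> list[SubstratePrediction]:
    return [predict(model, x) for x in np.atleast_2d(X)]


def predict_top(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Top-label prediction for each row (alphabetical tie-break)."""
    proba = model.predict_proba_matrix(X)
    vocab = np.array(model.label_vocabulary)
    return vocab[np.argmax(proba, axis=1)]  # argmax takes first = alphabetical


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist model + metadata; the header is validated on load."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "backend": model.backend,
        "scheme": model.scheme,
        "label_vocabulary": list(model.label_vocabulary),
        "weight_balanced": model.weight_balanced,
        "seed": model.seed,
        "n_features": model.n_features,
        "positions_hash": model.positions_hash,
    }
    meta["checksum"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()
    ).hexdigest()
    joblib.dump({"meta": meta, "estimator": model.estimator}, path)


def load_model(path: str | Path) -> ClassifierModel:
    payload = joblib.load(path)
    try:
        meta = payload["meta"]
        estimator = payload["estimator"]
        checksum = meta.pop("checksum")
    except (KeyError, TypeError) as exc:
        raise ValueError(f"corrupted model file {path}: missing header") from exc
    expected = hashlib.sha256(json.dumps(meta, sort_keys=True).encode()).hexdigest()
    if checksum != expected:
        raise ValueError(f"corrupted model file {path}: checksum mismatch")
    if meta["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return ClassifierModel(
        backend=meta["backend"],
        scheme=meta["scheme"],
        label_vocabulary=tuple(meta["label_vocabulary"]),
        weight_balanced=meta["weight_balanced"],
        seed=meta["seed"],
        estimator=estimator,
        n_features=meta["n_features"],
        positions_hash=meta["positions_hash"],
    )
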
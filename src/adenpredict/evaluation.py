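"""Repeated-holdout evaluation and Hamming-distance generalization buckets.

Overall test accuracy hides how badly a signature classifier degrades on
*novel* A-domains — those far from anything in the training set. To expose
this, each test point is bucketed by its minimum Hamming distance ``k`` to
the training signatures: bucket ``Bk`` holds the points at distance exactly
``k``, and the cumulative bucket ``Bk+`` those at distance at least ``k``.
Accuracy is then reported per bucket, pooled over repeated 80:20 random
shuffles of the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._constants import SIGNATURE_LENGTH
from .encodings import EncodingScheme, encode_all, get_scheme
from .signatures import LabeledSignature, Signature
from .specificity import predict_top, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Repeated random train/test split: repeat ``r`` uses seed ``base_seed + r``."""

    train_fraction: float = 0.8
    n_repeats: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


def hamming(a: Signature | str, b: Signature | str) -> int:
    """Positions at which two signatures differ ('-'/'X' compared literally)."""
    sa = a.residues if isinstance(a, Signature) else a
    sb = b.residues if isinstance(b, Signature) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


def _as_byte_matrix(signatures: Sequence[Signature | str]) -> np.ndarray:
    strings = [
        s.residues if isinstance(s, Signature) else s for s in signatures
    ]
    if any(len(s) != SIGNATURE_LENGTH for s in strings):
        raise ValueError(f"all signatures must have length {SIGNATURE_LENGTH}")
    return np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8).reshape(
        len(strings), SIGNATURE_LENGTH
    )


@dataclass(frozen=True)
class BucketAssignment:
    """Minimum Hamming distance of each test point to the training set."""

    k: np.ndarray  # shape (n_test,), integer distances in [0, 34]

    def members(self, k: int) -> np.ndarray:
        """Indices of test points in bucket ``Bk`` (distance exactly k)."""
        return np.flatnonzero(self.k == k)

    def members_at_least(self, k: int) -> np.ndarray:
        """Indices of test points in cumulative bucket ``Bk+``."""
        return np.flatnonzero(self.k >= k)

    def bucket_sizes(self) -> dict[int, int]:
        ks, counts = np.unique(self.k, return_counts=True)
        return {int(k): int(c) for k, c in zip(ks, counts)}


def assign_buckets(
    test: Sequence[Signature | str], train: Sequence[Signature | str]
) -> BucketAssignment:
    """Compute each test signature's minimum Hamming distance to the training set."""
    if len(train) == 0:
        raise ValueError("training set must be non-empty")
    if len(test) == 0:
        return BucketAssignment(np.empty(0, dtype=int))
    T = _as_byte_matrix(test)
    R = _as_byte_matrix(train)
    # chunk over test rows to bound the (chunk, n_train, 34) broadcast
    mins = np.empty(len(T), dtype=int)
    step = max(1, 2_000_000 // max(1, len(R)))
    for i in range(0, len(T), step):
        diff = T[i : i + step, None, :] != R[None, :, :]
        mins[i : i + step] = diff.sum(axis=2).min(axis=1)
    return BucketAssignment(mins)


def per_class_f1(
    confusion: np.ndarray, labels: Sequence[str]
) -> dict[str, float]:
    """Per-class F1 from a confusion matrix (rows = true, columns = predicted).

    F1 is 0 by convention for a class with zero precision and recall
    (including classes never seen and never predicted).
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if confusion.shape[0] != len(labels):
        raise ValueError("label list does not match matrix size")
    out: dict[str, float] = {}
    for i, label in enumerate(labels):
        tp = confusion[i, i]
        fn = confusion[i, :].sum() - tp
        fp = confusion[:, i].sum() - tp
        denom = 2 * tp + fp + fn
        out[label] = float(2 * tp / denom) if denom > 0 else 0.0
    return out


@dataclass
class EvaluationReport:
    """Pooled results of repeated-holdout evaluation."""

    overall_accuracy: float
    per_repeat_accuracy: list[float]
    per_bucket_accuracy: dict[int, tuple[float, int]]  # k -> (accuracy, n)
    confusion_matrix: np.ndarray  # rows = true, cols = predicted
    labels: tuple[str, ...]
    per_class_f1: dict[str, float]
    n_repeats: int
    n_test_total: int

    def cumulative_bucket_accuracy(self, k: int) -> tuple[float, int]:
        """Accuracy over the pooled cumulative bucket ``Bk+``."""
        hits = sum(
            acc * n for kk, (acc, n) in self.per_bucket_accuracy.items() if kk >= k
        )
        n = sum(n for kk, (_, n) in self.per_bucket_accuracy.items() if kk >= k)
        return (hits / n if n else float("nan"), n)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_repeat_accuracy": self.per_repeat_accuracy,
            "per_bucket_accuracy": {
                str(k): {"accuracy": acc, "n": n}
                for k, (acc, n) in sorted(self.per_bucket_accuracy.items())
            },
            "labels": list(self.labels),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class_f1": {k: self.per_class_f1[k] for k in sorted(self.per_class_f1)},
            "n_repeats": self.n_repeats,
            "n_test_total": self.n_test_total,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def evaluate(
    dataset: Sequence[LabeledSignature],
    scheme: str | EncodingScheme = "onehot",
    backend: str = "extra_trees",
    weight_balanced: bool = False,
    split: SplitSpec | None = None,
    hyperparams: Mapping | None = None,
) -> EvaluationReport:
    """Repeated-holdout evaluation with pooled bucket and confusion statistics.

    For each repeat the dataset is split at random (unstratified) into
    train/test, the training part is encoded and fitted, and test predictions
    are accumulated. Bucket distances are computed on raw signature strings,
    so bucket membership does not depend on the encoding scheme. Per-bucket
    accuracies, the confusion matrix and per-class F1 are pooled over all
    repeats; the overall accuracy is the mean of per-repeat accuracies.

    A repeat whose training split collapses to a single class is re-drawn
    with a shifted seed (logged). Test points whose true class is absent
    from their training split count as errors.
    """
    if split is None:
        split = SplitSpec()
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    n = len(dataset)
    n_train = int(round(split.train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"dataset of size {n} cannot be split with train_fraction "
            f"{split.train_fraction}"
        )

    signatures = [d.signature.residues for d in dataset]
    labels = np.array([d.label for d in dataset])
    X = encode_all(signatures, scheme)
    vocab = tuple(sorted(set(labels)))
    lab_index = {l: i for i, l in enumerate(vocab)}

    confusion = np.zeros((len(vocab), len(vocab)), dtype=int)
    bucket_hits: dict[int, int] = {}
    bucket_totals: dict[int, int] = {}
    per_repeat_acc: list[float] = []

    for r in range(split.n_repeats):
        seed = split.base_seed + r
        for attempt in range(100):
            rng = np.random.default_rng(seed + 1_000_003 * attempt)
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(set(labels[tr])) >= 2:
                break
            logger.warning("repeat %d: single-class training split, re-drawn", r)
        else:
            raise ValueError("could not draw a training split with >= 2 classes")

        model = train(
            X[tr],
            labels[tr],
            backend=backend,
            weight_balanced=weight_balanced,
            seed=seed,
            scheme=scheme.name,
            hyperparams=hyperparams,
        )
        pred = predict_top(model, X[te])
        correct = pred == labels[te]
        per_repeat_acc.append(float(correct.mean()))

        ks = assign_buckets([signatures[i] for i in te], [signatures[i] for i in tr]).k
        for k, ok in zip(ks, correct):
            bucket_totals[int(k)] = bucket_totals.get(int(k), 0) + 1
            bucket_hits[int(k)] = bucket_hits.get(int(k), 0) + bool(ok)
        for true, p in zip(labels[te], pred):
            confusion[lab_index[true], lab_index[p]] += 1

    per_bucket = {
        k: (bucket_hits[k] / bucket_totals[k], bucket_totals[k])
        for k in sorted(bucket_totals)
    }
    return EvaluationReport(
        overall_accuracy=float(np.mean(per_repeat_acc)),
        per_repeat_accuracy=per_repeat_acc,
        per_bucket_accuracy=per_bucket,
        confusion_matrix=confusion,
        labels=vocab,
        per_class_f1=per_class_f1(confusion, vocab),
        n_repeats=split.n_repeats,
        n_test_total=int(confusion.sum()),
    )
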
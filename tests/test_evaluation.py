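"""Hamming buckets, repeated-holdout evaluation, confusion-matrix metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adenpredict import AMINO_ACIDS, synthgen
from adenpredict.evaluation import (
    SplitSpec,
    assign_buckets,
    evaluate,
    hamming,
    per_class_f1,
)
from adenpredict.signatures import LabeledSignature, Signature

signature_strings = st.text(alphabet=AMINO_ACIDS + "-X", min_size=34, max_size=34)

FAST = {"n_estimators": 100}


def _random_signatures(n, rng):
    return [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 34)) for _ in range(n)
    ]


class TestHamming:
    def test_identical_zero(self):
        assert hamming("A" * 34, "A" * 34) == 0

    def test_fully_different(self):
        assert hamming("A" * 34, "C" * 34) == 34

    @settings(max_examples=100, derandomize=True)
    @given(signature_strings, signature_strings)
    def test_matches_brute_force(self, a, b):
        assert hamming(a, b) == sum(x != y for x, y in zip(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hamming("A" * 34, "A" * 33)


class TestAssignBuckets:
    def test_train_member_has_k_zero(self):
        rng = np.random.default_rng(0)
        train = _random_signatures(20, rng)
        ks = assign_buckets([train[3]], train).k
        assert ks.tolist() == [0]

    def test_membership_structure(self):
        rng = np.random.default_rng(1)
        train = _random_signatures(50, rng)
        test = _random_signatures(10, rng)
        ba = assign_buckets(test, train)
        for i, k in enumerate(ba.k):
            assert i in ba.members(int(k))
            for j in range(int(k) + 1):
                assert i in ba.members_at_least(j)
            assert i not in ba.members_at_least(int(k) + 1)

    def test_bucket_partition_and_monotone_cumulative(self):
        rng = np.random.default_rng(2)
        train = _random_signatures(80, rng)
        test = _random_signatures(40, rng)
        ba = assign_buckets(test, train)
        assert sum(ba.bucket_sizes().values()) == len(test)
        sizes = [len(ba.members_at_least(k)) for k in range(35)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        train = _random_signatures(200, rng)
        test = _random_signatures(50, rng)
        ks = assign_buckets(test, train).k
        oracle = [
            min(sum(a != b for a, b in zip(t, tr)) for tr in train) for t in test
        ]
        assert ks.tolist() == oracle

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            assign_buckets(["A" * 34], [])


class TestPerClassF1:
    def test_diagonal_matrix_all_ones(self):
        f1 = per_class_f1(np.diag([5, 3, 2]), ["a", "b", "c"])
        assert all(v == 1.0 for v in f1.values())

    def test_absent_class_zero(self):
        confusion = np.array([[4, 0], [0, 0]])
        f1 = per_class_f1(confusion, ["a", "b"])
        assert f1["b"] == 0.0

    def test_hand_computed_binary_case(self):
        confusion = np.array([[8, 2], [1, 9]])
        f1 = per_class_f1(confusion, ["x", "y"])
        precision, recall = 8 / 9, 8 / 10
        assert f1["x"] == pytest.approx(
            2 * precision * recall / (precision + recall)
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            per_class_f1(np.zeros((2, 3)), ["a", "b"])


class TestEvaluate:
    def test_separable_dataset_perfect_everywhere(self):
        spec = synthgen.SynthSpec.balanced(4, 30, n_motif=12, seed=10)
        data = synthgen.generate(spec)
        report = evaluate(
            data, split=SplitSpec(n_repeats=3, base_seed=1), hyperparams=FAST
        )
        assert report.overall_accuracy == 1.0
        assert all(acc == 1.0 for acc, _ in report.per_bucket_accuracy.values())

    def test_confusion_bookkeeping(self):
        spec = synthgen.SynthSpec.balanced(4, 25, n_motif=10, motif_strength=0.8, seed=11)
        data = synthgen.generate(spec)
        n_test = len(data) - int(round(0.8 * len(data)))
        report = evaluate(
            data, split=SplitSpec(n_repeats=4, base_seed=2), hyperparams=FAST
        )
        assert report.confusion_matrix.sum() == 4 * n_test
        assert report.n_test_total == 4 * n_test
        assert sum(n for _, n in report.per_bucket_accuracy.values()) == 4 * n_test

    def test_shuffled_labels_give_chance_accuracy(self):
        spec = synthgen.SynthSpec.balanced(4, 40, n_motif=12, seed=12)
        data = synthgen.generate(spec)
        rng = np.random.default_rng(99)
        labels = [d.label for d in data]
        shuffled = [
            LabeledSignature(d.signature, labels[i])
            for d, i in zip(data, rng.permutation(len(data)))
        ]
        report = evaluate(
            shuffled, split=SplitSpec(n_repeats=5, base_seed=3), hyperparams=FAST
        )
        n = report.n_test_total
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(report.overall_accuracy - 0.25) < 3 * se

    def test_novel_points_harder_than_near_duplicates(self):
        """Accuracy decays with distance from the training set once motifs
        are only partially conserved."""
        spec = synthgen.SynthSpec.balanced(
            6, 50, n_motif=20, motif_strength=0.55, seed=13
        )
        data = synthgen.generate(spec)
        report = evaluate(
            data, split=SplitSpec(n_repeats=5, base_seed=4), hyperparams=FAST
        )
        near = [
            (acc, n) for k, (acc, n) in report.per_bucket_accuracy.items() if k <= 5
        ]
        far = [
            (acc, n) for k, (acc, n) in report.per_bucket_accuracy.items() if k >= 21
        ]
        if near and far:
            mean = lambda rows: sum(a * n for a, n in rows) / sum(n for _, n in rows)
            assert mean(far) <= mean(near)

    def test_too_small_dataset_rejected(self):
        data = [
            LabeledSignature(Signature("A" * 34), "a"),
        ]
        with pytest.raises(ValueError, match="split"):
            evaluate(data)

    def test_report_serialization_sorted(self):
        spec = synthgen.SynthSpec.balanced(3, 15, n_motif=10, seed=14)
        data = synthgen.generate(spec)
        report = evaluate(
            data, split=SplitSpec(n_repeats=2, base_seed=5), hyperparams=FAST
        )
        text = report.to_json()
        assert text == report.to_json()
        import json

        doc = json.loads(text)
        assert list(doc["per_class_f1"]) == sorted(doc["per_class_f1"])
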
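"""Classifier harness: sample weighting, training, prediction, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adenpredict import synthgen
from adenpredict.encodings import encode_all, onehot_scheme
from adenpredict.specificity import (
    ClassifierModel,
    compute_sample_weights,
    load_model,
    predict,
    predict_top,
    save_model,
    train,
)

FAST_TREES = {"n_estimators": 100}


def _encoded(spec):
    data = synthgen.generate(spec)
    X = encode_all([d.signature for d in data], onehot_scheme())
    y = np.array([d.label for d in data])
    return X, y


class TestSampleWeights:
    def test_direct_values(self):
        np.testing.assert_allclose(
            compute_sample_weights(["phe", "phe", "ser"]), [0.5, 0.5, 1.0]
        )

    def test_all_distinct_weights_one(self):
        assert (compute_sample_weights(list("abcd")) == 1.0).all()

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=60))
    def test_per_class_sums_equal_one(self, labels):
        """Every class contributes exactly 1 to the weighted loss."""
        labels = [f"c{i}" for i in labels]
        w = compute_sample_weights(labels)
        for c in set(labels):
            total = sum(wi for wi, y in zip(w, labels) if y == c)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_sample_weights([])


class TestTrain:
    def test_separable_data_memorized(self):
        spec = synthgen.SynthSpec.balanced(2, 30, n_motif=12, seed=1)
        X, y = _encoded(spec)
        model = train(X, y, hyperparams=FAST_TREES)
        assert (predict_top(model, X) == y).mean() == 1.0

    def test_same_seed_identical_predictions(self):
        spec = synthgen.SynthSpec.balanced(3, 20, n_motif=8, motif_strength=0.7, seed=2)
        X, y = _encoded(spec)
        probe = X[::5]
        p1 = predict_top(train(X, y, seed=9, hyperparams=FAST_TREES), probe)
        p2 = predict_top(train(X, y, seed=9, hyperparams=FAST_TREES), probe)
        assert (p1 == p2).all()

    def test_single_label_rejected(self):
        X = np.zeros((5, 680))
        with pytest.raises(ValueError, match="2 distinct labels"):
            train(X, ["phe"] * 5)

    @pytest.mark.parametrize("backend", ["knn", "mlp"])
    def test_unweightable_backend_rejects_balance(self, backend):
        X = np.zeros((6, 4))
        y = ["a", "b", "a", "b", "a", "b"]
        with pytest.raises(ValueError, match=backend):
            train(X, y, backend=backend, weight_balanced=True)

    def test_gnn_backend_unsupported(self):
        with pytest.raises(ValueError, match="unsupported"):
            train(np.zeros((4, 2)), ["a", "b", "a", "b"], backend="gnn")

    def test_balancing_raises_minority_recall(self):
        """On overlapping 90:10 data the balanced model recovers more of the
        minority class than the unbalanced one."""
        spec = synthgen.SynthSpec(
            n_classes=2,
            n_per_class=(450, 50),
            motif_positions=tuple(range(1, 7)),
            motif_strength=0.5,
            seed=0,
        )
        X, y = _encoded(spec)
        rng = np.random.default_rng(100)
        perm = rng.permutation(len(y))
        tr, te = perm[:400], perm[400:]
        recalls = {}
        for bal in (False, True):
            model = train(X[tr], y[tr], weight_balanced=bal, seed=0,
                          hyperparams={"n_estimators": 300})
            pred = predict_top(model, X[te])
            mask = y[te] == "sub01"
            recalls[bal] = (pred[mask] == "sub01").mean()
        assert recalls[True] > recalls[False]


@pytest.fixture(scope="module")
def model():
    spec = synthgen.SynthSpec.balanced(3, 25, n_motif=10, seed=3)
    data = synthgen.generate(spec)
    X = encode_all([d.signature for d in data], onehot_scheme())
    return train(X, [d.label for d in data], hyperparams=FAST_TREES), data


class TestPredict:
    def test_probabilities_normalized_and_sorted(self, model):
        m, data = model
        X = encode_all([d.signature for d in data[:10]], onehot_scheme())
        for row in X:
            pred = predict(m, row)
            scores = [s for _, s in pred.ranked]
            assert sum(scores) == pytest.approx(1.0, abs=1e-6)
            assert scores == sorted(scores, reverse=True)
            assert all(0.0 <= s <= 1.0 for s in scores)

    def test_top_matches_training_pattern(self, model):
        m, data = model
        x = encode_all([data[0].signature], onehot_scheme())[0]
        assert predict(m, x).top == data[0].label

    def test_alphabetical_tie_break(self):
        model = ClassifierModel(
            backend="stub", scheme="onehot", label_vocabulary=("ala", "zzz"),
            weight_balanced=False, seed=0, estimator=None, n_features=2,
        )

        class Stub:
            classes_ = np.array(["ala", "zzz"])

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        model.estimator = Stub()
        assert predict(model, np.zeros(2)).top == "ala"

    def test_feature_length_guard(self, model):
        m, _ = model
        with pytest.raises(ValueError, match="does not match"):
            predict(m, np.zeros(510))

    def test_softmax_backend_normalized(self):
        spec = synthgen.SynthSpec.balanced(3, 15, n_motif=10, seed=4)
        data = synthgen.generate(spec)
        X = encode_all([d.signature for d in data], onehot_scheme())
        m = train(X, [d.label for d in data], backend="ridge")
        pred = predict(m, X[0])
        assert sum(s for _, s in pred.ranked) == pytest.approx(1.0, abs=1e-6)


class TestPersistence:
    def test_round_trip_identical_predictions(self, tmp_path):
        spec = synthgen.SynthSpec.balanced(3, 20, n_motif=10, seed=6)
        data = synthgen.generate(spec)
        X = encode_all([d.signature for d in data], onehot_scheme())
        model = train(X, [d.label for d in data], hyperparams=FAST_TREES)
        path = tmp_path / "model.bin"
        save_model(model, path)
        loaded = load_model(path)
        for row in X[::7]:
            assert predict(loaded, row).ranked == predict(model, row).ranked
        assert loaded.scheme == model.scheme
        assert loaded.label_vocabulary == model.label_vocabulary

    def test_corrupted_header_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "bad.bin"
        joblib.dump({"something": "else"}, path)
        with pytest.raises(ValueError, match="header"):
            load_model(path)

    def test_scheme_mismatch_guard(self, tmp_path):
        """A model persisted with one-hot features rejects a probe of
        physiochemical length."""
        spec = synthgen.SynthSpec.balanced(2, 15, n_motif=8, seed=8)
        data = synthgen.generate(spec)
        X = encode_all([d.signature for d in data], onehot_scheme())
        model = train(X, [d.label for d in data], hyperparams=FAST_TREES)
        path = tmp_path / "model.bin"
        save_model(model, path)
        loaded = load_model(path)
        with pytest.raises(ValueError, match="onehot"):
            predict(loaded, np.zeros(510))
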
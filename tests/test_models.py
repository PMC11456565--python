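"""Balancing, scaling, splitting, sequence building, and training sanity."""

import numpy as np
import pytest

from turnload import models
from turnload.models import (
    MinMaxScaler01,
    TrainConfig,
    build_lstm,
    build_lstm_attention,
    make_sequences,
    normalize01,
    split,
    train_baselines,
    train_model,
    upsample_balance,
)


class TestUpsampleBalance:
    def _data(self, counts, seed=0):
        y = np.concatenate([np.full(c, cid) for cid, c in counts.items()])
        X = np.arange(len(y), dtype=float)[:, None] + 100 * y[:, None]
        return X, y

    def test_counts_equalized(self):
        X, y = self._data({1: 10, 2: 5, 3: 2})
        Xb, yb = upsample_balance(X, y, seed=1)
        _, counts = np.unique(yb, return_counts=True)
        assert list(counts) == [10, 10, 10]

    def test_balanced_input_unchanged(self):
        X, y = self._data({1: 4, 2: 4, 3: 4})
        Xb, yb = upsample_balance(X, y, seed=1)
        assert sorted(map(tuple, Xb)) == sorted(map(tuple, X))

    def test_outputs_are_copies_of_inputs(self):
        X, y = self._data({1: 6, 2: 3, 3: 2})
        Xb, yb = upsample_balance(X, y, seed=2)
        originals = {(float(r[0]), int(c)) for r, c in zip(X, y)}
        for r, c in zip(Xb, yb):
            assert (float(r[0]), int(c)) in originals

    def test_class_means_preserved_in_expectation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = np.r_[np.full(40, 1), np.full(15, 2), np.full(5, 3)]
        diffs = []
        for seed in range(40):
            Xb, yb = upsample_balance(X, y, seed=seed)
            diffs.append(Xb[yb == 3].mean(axis=0) - X[y == 3].mean(axis=0))
        assert np.abs(np.mean(diffs, axis=0)).max() < 0.2


class TestNormalize01:
    def test_basic_scaling(self):
        tr = np.array([[2.0], [4.0], [6.0]])
        out, applied, scaler = normalize01(tr, tr)
        assert np.allclose(out.ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        tr = np.full((4, 1), 7.0)
        out, _, _ = normalize01(tr, tr)
        assert np.all(out == 0)

    def test_out_of_range_test_values_allowed(self):
        tr = np.array([[0.0], [10.0]])
        te = np.array([[-5.0], [15.0]])
        _, applied, _ = normalize01(tr, te)
        assert applied.min() < 0 and applied.max() > 1

    def test_sequence_axes_share_feature_scaling(self):
        X = np.arange(24, dtype=float).reshape(4, 3, 2)
        out, _, _ = normalize01(X, X)
        assert out.min() == 0 and out.max() == 1


class TestSplit:
    def test_seventy_thirty_disjoint_exhaustive(self):
        X = np.arange(100, dtype=float)[:, None]
        y = np.r_[np.full(50, 1), np.full(30, 2), np.full(20, 3)]
        Xtr, Xte, ytr, yte = split(X, y, seed=0)
        assert len(ytr) == 70 and len(yte) == 30
        assert sorted(np.r_[Xtr.ravel(), Xte.ravel()]) == sorted(X.ravel())

    def test_same_seed_same_split(self):
        X = np.arange(40, dtype=float)[:, None]
        y = np.r_[np.full(20, 1), np.full(10, 2), np.full(10, 3)]
        a = split(X, y, seed=5)
        b = split(X, y, seed=5)
        assert np.array_equal(a[0], b[0])

    def test_tiny_class_rejected(self):
        y = np.r_[np.full(9, 1), [2]]
        with pytest.raises(ValueError):
            split(np.zeros((10, 1)), y)


class TestMakeSequences:
    def test_sequences_stay_within_segments(self, small_features):
        features, _ = small_features
        X, y, subj = make_sequences(features, ["rmssd", "sdnn"], seq_len=3)
        assert X.shape[1:] == (3, 2)
        assert set(np.unique(y)) <= {1, 2, 3}
        assert len(X) == len(y) == len(subj)
        assert len(X) > 0


def _separable(n_per_class=60, seq_len=3, n_feat=4, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in (1, 2, 3):
        centers = np.zeros(n_feat)
        centers[c - 1] = 3.0
        X.append(rng.normal(centers, 0.3, size=(n_per_class, seq_len, n_feat)))
        y.append(np.full(n_per_class, c))
    return np.concatenate(X), np.concatenate(y)


class TestTraining:
    def test_learns_separable_classes(self):
        X, y = _separable()
        X01 = (X - X.min()) / (X.max() - X.min())
        cfg = TrainConfig(seed=1, batch_size=32)
        model = build_lstm_attention(4, cfg)
        history = train_model(model, X01, y, cfg)
        assert (model.predict(X01) == y).mean() > 0.95
        assert history["epochs_run"] <= cfg.max_epochs == 50

    def test_divergence_raises(self):
        X, y = _separable(n_per_class=20)
        X[0, 0, 0] = np.nan  # poisoned input drives the loss non-finite
        cfg = TrainConfig(seed=1, max_epochs=3)
        model = build_lstm(4, cfg)
        with pytest.raises(FloatingPointError):
            train_model(model, X, y, cfg)

    def test_architectures_differ_only_by_attention(self):
        att = build_lstm_attention(7, TrainConfig(seed=0))
        plain = build_lstm(7, TrainConfig(seed=0))
        # identical first two layers and head dimensions
        assert att.lstm1.params.W_f.shape == plain.lstm1.params.W_f.shape
        assert att.lstm2.params.W_f.shape == plain.lstm2.params.W_f.shape
        assert att.dense1.W.shape == plain.dense1.W.shape
        # third layer consumes [h, context] in the attention variant
        assert att.lstm3.params.W_f.shape[0] - att.lstm3.hidden == 2 * plain.lstm2.hidden
        extra = att.n_parameters() - plain.n_parameters()
        att_params = att.att.W.data.size + att.att.b.data.size
        lstm3_delta = 4 * plain.lstm3.hidden * plain.lstm2.hidden
        assert extra == att_params + lstm3_delta


class TestBaselines:
    def test_probabilities_over_three_classes(self):
        X, y = _separable(n_per_class=10)
        for model in train_baselines(X, y, seed=0).values():
            prob = model.predict_proba(X)
            assert prob.shape == (len(y), 3)
            assert np.allclose(prob.sum(axis=1), 1.0)

    def test_knn_k1_memorizes_training_set(self):
        X, y = _separable(n_per_class=15, seed=3)
        knn = train_baselines(X, y, seed=0, n_neighbors=1)["KNN"]
        assert (knn.predict(X) == y).mean() == 1.0

    def test_rf_deterministic_per_seed(self):
        X, y = _separable(n_per_class=15, seed=4)
        a = train_baselines(X, y, seed=9)["RF"].predict_proba(X)
        b = train_baselines(X, y, seed=9)["RF"].predict_proba(X)
        assert np.array_equal(a, b)
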
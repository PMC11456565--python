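"""Autodiff, LSTM cell, attention: closed forms and gradient checks."""

import numpy as np
import pytest

from turnload import nn
from turnload.models import TrainConfig, build_lstm_attention
from turnload.nn import (
    AttentionParams,
    LSTMCellParams,
    Tensor,
    attention,
    lstm_cell_step,
)


def zero_cell(hidden, inputs):
    z = lambda: Tensor(np.zeros((hidden + inputs, hidden)))
    b = lambda: Tensor(np.zeros(hidden))
    return LSTMCellParams(W_f=z(), W_i=z(), W_a=z(), W_o=z(),
                          b_f=b(), b_i=b(), b_a=b(), b_o=b())


class TestLSTMCell:
    def test_zero_parameters_closed_form(self):
        """With all weights/biases zero: f=i=o=1/2, C=C_prev/2, h=o*tanh(C)."""
        params = zero_cell(3, 2)
        C_prev = np.array([[0.4, -0.6, 1.0]])
        h, C = lstm_cell_step(params, np.zeros((1, 3)), C_prev, np.ones((1, 2)))
        assert np.allclose(C, 0.5 * C_prev)
        assert np.allclose(h, 0.5 * np.tanh(0.5 * C_prev))

    def test_scalar_hand_computed(self):
        """Single unit, hand-set scalar weights, one input."""
        w = lambda v: Tensor(np.array([[v], [v]]))  # acts on [h_prev, x]
        params = LSTMCellParams(
            W_f=w(0.5), W_i=w(-0.25), W_a=w(1.0), W_o=w(0.75),
            b_f=Tensor([0.1]), b_i=Tensor([0.2]), b_a=Tensor([0.0]), b_o=Tensor([-0.1]),
        )
        h_prev, C_prev, x = 0.3, -0.2, 0.8
        sig = lambda z: 1 / (1 + np.exp(-z))
        f = sig(0.5 * (h_prev + x) + 0.1)
        i = sig(-0.25 * (h_prev + x) + 0.2)
        a = np.tanh(1.0 * (h_prev + x))
        C = f * C_prev + i * a
        o = sig(0.75 * (h_prev + x) - 0.1)
        h_expect = o * np.tanh(C)
        h, C_got = lstm_cell_step(
            params, np.array([[h_prev]]), np.array([[C_prev]]), np.array([[x]])
        )
        assert h[0, 0] == pytest.approx(h_expect, rel=1e-12)
        assert C_got[0, 0] == pytest.approx(C, rel=1e-12)

    def test_gates_bounded(self):
        rng = np.random.default_rng(0)
        params = zero_cell(4, 3)
        for t in params.all():
            t.data = rng.normal(0, 2, t.data.shape)
        h, C = lstm_cell_step(params, rng.normal(size=(5, 4)),
                              rng.normal(size=(5, 4)), rng.normal(size=(5, 3)))
        assert np.all(np.abs(h) < 1.0)  # h = o * tanh(C), both factors in (-1, 1)

    def test_shape_mismatch_rejected(self):
        params = zero_cell(3, 2)
        with pytest.raises(ValueError):
            lstm_cell_step(params, np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 5)))


class TestAttention:
    def _params(self, hidden, w=0.0, b=0.0):
        return AttentionParams(W=Tensor(np.full((hidden, 1), w)), b=Tensor([b]))

    def test_equal_scores_uniform_weights(self):
        H = [np.ones((4, 3)) for _ in range(5)]
        a, V = attention(H, self._params(3))
        assert np.allclose(a, 1 / 5)
        assert np.allclose(V, 1.0)

    def test_weights_form_probability_vector(self):
        rng = np.random.default_rng(1)
        H = [rng.normal(size=(6, 4)) for _ in range(7)]
        params = AttentionParams(W=Tensor(rng.normal(size=(4, 1))), b=Tensor([0.3]))
        a, V = attention(H, params)
        assert np.all(a > 0)
        assert np.allclose(a.sum(axis=1), 1.0)

    def test_dominant_score_selects_position(self):
        """A score gap of ~20 makes the context converge to that step's h."""
        H = [Tensor(np.full((1, 2), v)) for v in (0.0, 0.0, 1.0)]
        # tanh saturates, so build the gap directly in the score tensor
        scores = np.array([[-10.0, -10.0, 10.0]])
        a = nn.softmax(Tensor(scores), axis=1)
        V = sum(a.data[0, t] * H[t].data for t in range(3))
        assert np.allclose(V, H[2].data, atol=1e-8)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            attention([], self._params(3))


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        """End-to-end gradient check of the full LSTM-Attention graph."""
        cfg = TrainConfig(lstm_units=(3, 3, 4), dense_units=3, seed=7)
        model = build_lstm_attention(2, cfg)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 3, 2))
        y = np.array([0, 1, 2, 1])

        loss = model.loss(X, y, l2=0.01)
        loss.backward()
        params = model.parameters()
        grads = [p.grad.copy() for p in params]

        eps = 1e-6
        rng2 = np.random.default_rng(3)
        for p, g in zip(params, grads):
            flat = p.data.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(model.loss(X, y, l2=0.01).data)
                flat[idx] = orig - eps
                down = float(model.loss(X, y, l2=0.01).data)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_softmax_head_rows_sum_to_one(self):
        model = build_lstm_attention(2, TrainConfig(lstm_units=(3, 3, 4), seed=0))
        X = np.random.default_rng(0).normal(size=(5, 3, 2))
        prob = model.predict_proba(X)
        assert prob.shape == (5, 3)
        assert np.allclose(prob.sum(axis=1), 1.0)

    def test_parameter_count_closed_form(self):
        """Parameter total matches the layer-dimension arithmetic at 7 inputs."""
        model = build_lstm_attention(7, TrainConfig(seed=0))
        lstm = lambda i, h: 4 * (h * (i + h) + h)
        expected = (
            lstm(7, 10) + lstm(10, 10)      # two sequence LSTMs
            + (10 + 1)                      # attention W and b
            + lstm(20, 20)                  # final LSTM on [h, context]
            + (20 * 6 + 6) + (6 * 3 + 3)    # dense layers
        )
        assert model.n_parameters() == expected == 4998
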
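"""Minimal reverse-mode autodiff and the recurrent building blocks.

The classifier at the heart of the project is an LSTM with a self-attention
layer.  Rather than pulling in a full deep-learning framework for three tiny
recurrent layers, this module implements exactly what the model needs: a
tape-based :class:`Tensor` (float64, 2-D activations), the LSTM cell
recurrence

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input gate)
    a~_t = tanh(W_a [h_{t-1}, x_t] + b_a)          (candidate values)
    C_t = f_t * C_{t-1} + i_t * a~_t               (cell state)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)

and additive self-attention over the hidden sequence H = (h_1 .. h_T):

    s_t = tanh(W^T h_t + b),  a = softmax(s),  V = sum_t a_t h_t.

Gradients are checked against finite differences in the test-suite, which is
the load-bearing correctness argument for everything here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() is defined for scalar losses only")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        a, b = self, other

        def bwd(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor(a.data + b.data, (a, b), bwd)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a, c = self, float(other)
            return Tensor(a.data * c, (a,), lambda g: a._accumulate(g * c))
        a, b = self, other

        def bwd(g):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        a, b = self, other

        def bwd(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor(a.data @ b.data, (a, b), bwd)


# -- elementwise nonlinearities ---------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(y, (x,), lambda g: x._accumulate(g * y * (1 - y)))


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor(y, (x,), lambda g: x._accumulate(g * (1 - y * y)))


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    return Tensor(y, (x,), lambda g: x._accumulate(g * (x.data > 0)))


# -- structural ops ----------------------------------------------------------


def concat(tensors, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(data, tuple(tensors), bwd)


def slice_col(x: Tensor, i: int) -> Tensor:
    def bwd(g):
        full = np.zeros_like(x.data)
        full[:, i : i + 1] = g
        x._accumulate(full)

    return Tensor(x.data[:, i : i + 1], (x,), bwd)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return Tensor(y, (x,), bwd)


def sum_squares(x: Tensor) -> Tensor:
    return Tensor(np.sum(x.data**2), (x,), lambda g: x._accumulate(2.0 * g * x.data))


def sum_squares_rows(x: Tensor, row_start: int) -> Tensor:
    """Sum of squares of ``x[row_start:]`` (partial-matrix L2 penalty)."""

    def bwd(g):
        full = np.zeros_like(x.data)
        full[row_start:] = 2.0 * g * x.data[row_start:]
        x._accumulate(full)

    return Tensor(np.sum(x.data[row_start:] ** 2), (x,), bwd)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    return Tensor(loss, (logits,), bwd)


# -- LSTM cell ---------------------------------------------------------------


@dataclass
class LSTMCellParams:
    """Gate weights acting on the concatenation [h_{t-1}, x_t].

    Each W has shape (hidden + input, hidden); each b has shape (hidden,).
    """

    W_f: Tensor
    W_i: Tensor
    W_a: Tensor
    W_o: Tensor
    b_f: Tensor
    b_i: Tensor
    b_a: Tensor
    b_o: Tensor

    def weights(self):
        return [self.W_f, self.W_i, self.W_a, self.W_o]

    def all(self):
        return self.weights() + [self.b_f, self.b_i, self.b_a, self.b_o]


def _lift(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def lstm_cell_step(params: LSTMCellParams, h_prev, C_prev, x_t):
    """One LSTM recurrence step; accepts Tensors or plain arrays.

    Returns ``(h_t, C_t)`` of the same kind as the inputs.
    """
    arrays = not isinstance(h_prev, Tensor)
    h_prev, C_prev, x_t = _lift(h_prev), _lift(C_prev), _lift(x_t)
    p = LSTMCellParams(*[_lift(w) for w in params.all()[:4]], *[_lift(b) for b in params.all()[4:]])
    if h_prev.shape[1] + x_t.shape[1] != p.W_f.shape[0]:
        raise ValueError("inconsistent hidden/input dimensions")
    hx = concat([h_prev, x_t], axis=1)
    f = sigmoid(hx @ p.W_f + p.b_f)
    i = sigmoid(hx @ p.W_i + p.b_i)
    a_tilde = tanh(hx @ p.W_a + p.b_a)
    C = f * C_prev + i * a_tilde
    o = sigmoid(hx @ p.W_o + p.b_o)
    h = o * tanh(C)
    return (h.data, C.data) if arrays else (h, C)


@dataclass
class AttentionParams:
    """Additive self-attention scoring parameters (score function: tanh)."""

    W: Tensor  # (hidden, 1)
    b: Tensor  # (1,)


def attention(H: list, params: AttentionParams):
    """Softmax-weighted pooling of a hidden-state sequence.

    ``H`` is the per-step hidden states (each (N, hidden)).  Returns the
    attention weights (N, T) and context vector V = sum_t a_t h_t (N, hidden).
    """
    if len(H) == 0:
        raise ValueError("empty hidden sequence")
    arrays = not isinstance(H[0], Tensor)
    H = [_lift(h) for h in H]
    W, b = _lift(params.W), _lift(params.b)
    scores = concat([tanh(h @ W + b) for h in H], axis=1)  # (N, T)
    a = softmax(scores, axis=1)
    V = None
    for t, h in enumerate(H):
        term = slice_col(a, t) * h
        V = term if V is None else V + term
    return (a.data, V.data) if arrays else (a, V)


# -- layers ------------------------------------------------------------------


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class LSTMLayer:
    """An LSTM layer unrolled over a sequence of (N, input_dim) steps."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.input_dim, self.hidden = input_dim, hidden

        def w():
            # recurrent block orthogonal, input block Glorot — keeps signal
            # flow healthy through the stacked recurrences
            return Tensor(
                np.vstack([orthogonal(rng, hidden), glorot(rng, input_dim, hidden)])
            )

        # forget-gate bias starts at 1 so early training does not flush state
        self.params = LSTMCellParams(
            W_f=w(), W_i=w(), W_a=w(), W_o=w(),
            b_f=Tensor(np.ones(hidden)), b_i=Tensor(np.zeros(hidden)),
            b_a=Tensor(np.zeros(hidden)), b_o=Tensor(np.zeros(hidden)),
        )

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        n = xs[0].shape[0]
        h = Tensor(np.zeros((n, self.hidden)))
        C = Tensor(np.zeros((n, self.hidden)))
        out = []
        for x in xs:
            h, C = lstm_cell_step(self.params, h, C, x)
            out.append(h)
        return out

    def weights(self):
        return self.params.weights()

    def l2_terms(self):
        # penalize the input (kernel) block only, not the recurrent block —
        # the usual reading of "L2 on the LSTM layers"
        return [sum_squares_rows(w, self.hidden) for w in self.params.weights()]

    def parameters(self):
        return self.params.all()


class DenseLayer:
    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, input_dim, units))
        self.b = Tensor(np.zeros(units))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def weights(self):
        return [self.W]

    def l2_terms(self):
        return [sum_squares(self.W)]

    def parameters(self):
        return [self.W, self.b]


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
                 clipnorm: float | None = 1.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        if self.clipnorm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clipnorm:
                scale = self.clipnorm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
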
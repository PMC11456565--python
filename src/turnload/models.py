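"""Turn-load classifiers and the training regimen.

The headline model stacks three LSTM layers with a self-attention layer:
LSTM(10, sequences) → LSTM(10, sequences) → attention over that output,
concatenated step-wise with it → LSTM(20, final state) → Dense(6, ReLU) →
Dense(3, softmax).  The plain-LSTM baseline is the same stack minus the
attention/concatenate stage; KNN and random-forest baselines operate on the
flattened window features.

Training follows a fixed regimen: features min-max scaled to [0, 1] (fitted
on the training set only), classes balanced by up-sampling (training set
only, after the split — balancing before splitting would leak duplicated
windows into the test set), Adam at learning rate 0.005 with batch size 150
for at most 50 epochs, L2 penalty 0.01 on all weight matrices, and early
stopping (patience 5) on a 15% validation split with best-weights restore.

Input samples are short sequences of consecutive overlapping feature windows
taken within a single turn, so the recurrent models see genuine short-term
time structure; the default sequence length is 3 windows (66 s of signal at
the default windowing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from . import nn
from .nn import (AttentionParams, DenseLayer, LSTMLayer, Tensor, attention,
                 concat, cross_entropy_logits, relu, softmax, sum_squares)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lstm_units: tuple[int, int, int] = (10, 10, 20)
    dense_units: int = 6
    output_units: int = 3
    batch_size: int = 150
    learning_rate: float = 0.005
    max_epochs: int = 50
    l2: float = 0.01
    train_frac: float = 0.7
    val_frac: float = 0.15
    patience: int = 5
    seq_len: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_frac < 1 or not 0 < self.val_frac < 1:
            raise ValueError("fractions must lie in (0, 1)")
        for v in (self.batch_size, self.max_epochs, self.patience, self.seq_len):
            if v < 1:
                raise ValueError("integer hyperparameters must be positive")


# ---------------------------------------------------------------------------
# sample construction


def make_sequences(
    features: pd.DataFrame, feature_names: list[str], seq_len: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, y, subjects) sequence samples from the labeled window table.

    Each sample is ``seq_len`` consecutive windows (by start time) belonging
    to the same subject and the same turn segment; its label is that turn's
    load class.  Returns X (n, seq_len, n_features), y (n,) in {1,2,3}, and
    the subject id per sample.
    """
    X, y, subj = [], [], []
    cols = ["subject", "segment_index", "start_s"]
    df = features.dropna(subset=["class_id"]).sort_values(cols)
    for (s, _seg), grp in df.groupby(["subject", "segment_index"]):
        mat = grp[feature_names].to_numpy(float)
        labels = grp["class_id"].to_numpy(int)
        for i in range(len(grp) - seq_len + 1):
            X.append(mat[i : i + seq_len])
            y.append(labels[i])
            subj.append(s)
    if not X:
        return np.empty((0, seq_len, len(feature_names))), np.empty(0, int), np.empty(0, int)
    return np.stack(X), np.array(y, int), np.array(subj, int)


def split(samples_X, samples_y, train_frac: float = 0.7, seed: int = 0):
    """Stratified random train/test split (disjoint and exhaustive)."""
    if len(samples_y) < 10:
        raise ValueError("need at least 10 samples to split")
    counts = pd.Series(samples_y).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    return train_test_split(
        samples_X,
        samples_y,
        train_size=train_frac,
        stratify=samples_y,
        random_state=seed,
    )


def upsample_balance(X, y, seed: int = 0):
    """Resample minority classes with replacement up to the majority count."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size == 0:
        raise ValueError("empty sample set")
    target = counts.max()
    rng = np.random.default_rng(seed)
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(members)
        extra = target - members.size
        if extra > 0:
            idx.append(rng.choice(members, size=extra, replace=True))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


@dataclass
class MinMaxScaler01:
    """Per-feature min-max scaler fitted on training data only.

    Constant features map to 0; out-of-range test values fall outside [0, 1]
    (allowed, logged once at transform time).
    """

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler01":
        flat = X.reshape(-1, X.shape[-1])
        mins = flat.min(axis=0)
        rng = flat.max(axis=0) - mins
        return cls(mins=mins, ranges=np.where(rng > 0, rng, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = (X - self.mins) / self.ranges
        if out.min() < 0 or out.max() > 1:
            logger.info("values outside the training range map outside [0, 1]")
        return out


def normalize01(train_X: np.ndarray, apply_X: np.ndarray):
    """Fit [0,1] scaling on ``train_X``; apply to both. Returns scaler too."""
    scaler = MinMaxScaler01.fit(train_X)
    return scaler.transform(train_X), scaler.transform(apply_X), scaler


# ---------------------------------------------------------------------------
# recurrent classifiers


class _SequenceModel:
    """Shared scaffolding: parameter bookkeeping, loss, prediction."""

    name = "sequence-model"

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def weights(self) -> list[Tensor]:
        raise NotImplementedError

    def forward(self, X: np.ndarray) -> Tensor:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward(X), axis=1).data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1) + 1  # classes are 1..3

    def l2_terms(self):
        raise NotImplementedError

    def loss(self, X: np.ndarray, y01: np.ndarray, l2: float) -> Tensor:
        out = cross_entropy_logits(self.forward(X), y01)
        if l2 > 0:
            penalty = None
            for sq in self.l2_terms():
                penalty = sq if penalty is None else penalty + sq
            out = out + penalty * l2
        return out

    def get_state(self):
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, d in zip(self.parameters(), state):
            p.data = d.copy()


class LSTMAttentionClassifier(_SequenceModel):
    """The three-layer LSTM with self-attention and step-wise concatenation."""

    name = "LSTM-Attention"

    def __init__(self, n_features: int, config: TrainConfig | None = None):
        cfg = config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        u1, u2, u3 = cfg.lstm_units
        self.lstm1 = LSTMLayer(n_features, u1, rng)
        self.lstm2 = LSTMLayer(u1, u2, rng)
        self.att = AttentionParams(W=Tensor(nn.glorot(rng, u2, 1)), b=Tensor(np.zeros(1)))
        self.lstm3 = LSTMLayer(2 * u2, u3, rng)
        self.dense1 = DenseLayer(u3, cfg.dense_units, rng)
        self.dense2 = DenseLayer(cfg.dense_units, cfg.output_units, rng)

    def forward(self, X: np.ndarray) -> Tensor:
        xs = [Tensor(X[:, t, :]) for t in range(X.shape[1])]
        h1 = self.lstm1.forward(xs)
        h2 = self.lstm2.forward(h1)
        _, context = attention(h2, self.att)
        merged = [concat([h, context], axis=1) for h in h2]
        h3 = self.lstm3.forward(merged)[-1]
        return self.dense2.forward(relu(self.dense1.forward(h3)))

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        xs = [Tensor(X[:, t, :]) for t in range(X.shape[1])]
        a, _ = attention(self.lstm2.forward(self.lstm1.forward(xs)), self.att)
        return a.data

    def parameters(self):
        return (
            self.lstm1.parameters() + self.lstm2.parameters() + self.lstm3.parameters()
            + [self.att.W, self.att.b]
            + self.dense1.parameters() + self.dense2.parameters()
        )

    def weights(self):
        return (
            self.lstm1.weights() + self.lstm2.weights() + self.lstm3.weights()
            + self.dense1.weights() + self.dense2.weights()
        )

    def l2_terms(self):
        return (
            self.lstm1.l2_terms() + self.lstm2.l2_terms() + self.lstm3.l2_terms()
            + self.dense1.l2_terms() + self.dense2.l2_terms()
        )


class LSTMClassifier(_SequenceModel):
    """Plain-LSTM baseline: the same stack minus attention/concatenate."""

    name = "LSTM"

    def __init__(self, n_features: int, config: TrainConfig | None = None):
        cfg = config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        u1, u2, u3 = cfg.lstm_units
        self.lstm1 = LSTMLayer(n_features, u1, rng)
        self.lstm2 = LSTMLayer(u1, u2, rng)
        self.lstm3 = LSTMLayer(u2, u3, rng)
        self.dense1 = DenseLayer(u3, cfg.dense_units, rng)
        self.dense2 = DenseLayer(cfg.dense_units, cfg.output_units, rng)

    def forward(self, X: np.ndarray) -> Tensor:
        xs = [Tensor(X[:, t, :]) for t in range(X.shape[1])]
        h3 = self.lstm3.forward(self.lstm2.forward(self.lstm1.forward(xs)))[-1]
        return self.dense2.forward(relu(self.dense1.forward(h3)))

    def parameters(self):
        return (
            self.lstm1.parameters() + self.lstm2.parameters() + self.lstm3.parameters()
            + self.dense1.parameters() + self.dense2.parameters()
        )

    def weights(self):
        return (
            self.lstm1.weights() + self.lstm2.weights() + self.lstm3.weights()
            + self.dense1.weights() + self.dense2.weights()
        )

    def l2_terms(self):
        return (
            self.lstm1.l2_terms() + self.lstm2.l2_terms() + self.lstm3.l2_terms()
            + self.dense1.l2_terms() + self.dense2.l2_terms()
        )


def build_lstm_attention(n_features: int, config: TrainConfig | None = None):
    return LSTMAttentionClassifier(n_features, config)


def build_lstm(n_features: int, config: TrainConfig | None = None):
    return LSTMClassifier(n_features, config)


def _fit_once(model: _SequenceModel, Xtr, ytr, Xval, yval, cfg: TrainConfig,
              shuffle_seed: int) -> dict:
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(shuffle_seed)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, since_best, since_lr_drop = np.inf, model.get_state(), 0, 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            loss = model.loss(Xtr[sel], ytr[sel], cfg.l2)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss.data})"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_loss = float(cross_entropy_logits(model.forward(Xval), yval).data)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_state, since_best, since_lr_drop = (
                val_loss, model.get_state(), 0, 0
            )
        else:
            since_best += 1
            since_lr_drop += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
            # 0.005 is the *initial* rate: halve it when validation stalls
            if since_lr_drop >= max(cfg.patience // 2, 1) and opt.lr > 1e-4:
                opt.lr *= 0.5
                since_lr_drop = 0
    model.set_state(best_state)
    history["epochs_run"] = len(history["train_loss"])
    history["best_val_loss"] = float(best_val)
    return history


def train_model(model: _SequenceModel, X: np.ndarray, y: np.ndarray,
                config: TrainConfig | None = None) -> dict:
    """Adam training with early stopping; returns the history dict.

    ``y`` uses class ids 1..3.  A stratified ``val_frac`` share of the
    training data is held out; when validation loss has not improved for
    ``patience`` epochs, training stops and the best weights are restored.
    The learning rate is halved when validation stalls (the configured rate
    is the initial one).  A run that never escapes chance level — an
    occasional failure mode of small recurrent nets from an unlucky
    initialization — is restarted from a reseeded initialization, up to
    ``restarts`` times.
    """
    cfg = config or TrainConfig()
    y01 = np.asarray(y, int) - 1
    Xtr, Xval, ytr, yval = train_test_split(
        X, y01, test_size=cfg.val_frac, stratify=y01, random_state=cfg.seed
    )
    chance = np.log(cfg.output_units)
    restarts = 3
    history = _fit_once(model, Xtr, ytr, Xval, yval, cfg, shuffle_seed=cfg.seed)
    attempt = 0
    while history["best_val_loss"] > 0.95 * chance and attempt < restarts:
        attempt += 1
        logger.warning("degenerate fit (val %.3f); restart %d", history["best_val_loss"], attempt)
        reinit = type(model)(
            model.lstm1.input_dim, replace(cfg, seed=cfg.seed + 1000 * attempt)
        )
        model.set_state(reinit.get_state())
        history = _fit_once(
            model, Xtr, ytr, Xval, yval, cfg, shuffle_seed=cfg.seed + 1000 * attempt
        )
    history["restarts"] = attempt
    return history


# ---------------------------------------------------------------------------
# conventional baselines


class FlattenedClassifier:
    """sklearn classifier on flattened (seq_len * n_features) vectors."""

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator

    @staticmethod
    def _flatten(X):
        return X.reshape(X.shape[0], -1)

    def fit(self, X, y):
        self.estimator.fit(self._flatten(X), y)
        return self

    def predict_proba(self, X):
        return self.estimator.predict_proba(self._flatten(X))

    def predict(self, X):
        return self.estimator.predict(self._flatten(X))


def train_baselines(X: np.ndarray, y: np.ndarray, seed: int = 0,
                    n_neighbors: int = 5, n_trees: int = 100) -> dict:
    """Fit the KNN and random-forest baselines on flattened sequences."""
    knn = FlattenedClassifier("KNN", KNeighborsClassifier(n_neighbors=n_neighbors)).fit(X, y)
    rf = FlattenedClassifier(
        "RF", RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    ).fit(X, y)
    return {"KNN": knn, "RF": rf}
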
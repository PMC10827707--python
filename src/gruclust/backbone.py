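"""Supervised recurrent feature extractor for tokenized DNA sequences.

The learning phase trains a recurrent network — a token embedding, 200 GRU
units (the final hidden state is used), a 128/64/32/16 relu stack with
dropout after each relu, and a one-unit sigmoid head — on the labelled
token matrices with binary cross-entropy, Adam, and early stopping.  After
training, the activations of an internal "latent" layer (by default the
fourth feature layer, the 32-unit relu) are extracted as the representation
that the prediction phase clusters.

The network is implemented on the NumPy engine in :mod:`gruclust._nn`;
``gru_cell_step`` below is an independent, direct transcription of the GRU
cell equations used for verification.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .preprocess import TokenizedDataset, Vocabulary


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# GRU cell contract
# ---------------------------------------------------------------------------

@dataclass
class GRUParams:
    """All weight/bias arrays of one GRU cell.

    ``W_*`` map the input (input_dim x hidden_dim), ``V_*`` map the previous
    hidden state (hidden_dim x hidden_dim), ``b_*`` are bias vectors.
    """

    W_z: np.ndarray
    W_r: np.ndarray
    W_C: np.ndarray
    V_z: np.ndarray
    V_r: np.ndarray
    V_C: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_C: np.ndarray

    def __post_init__(self) -> None:
        d, h = self.W_z.shape
        expect = {
            "W_z": (d, h), "W_r": (d, h), "W_C": (d, h),
            "V_z": (h, h), "V_r": (h, h), "V_C": (h, h),
            "b_z": (h,), "b_r": (h,), "b_C": (h,),
        }
        for name, shape in expect.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)

    @classmethod
    def zeros(cls, input_dim: int, hidden_dim: int) -> "GRUParams":
        d, h = input_dim, hidden_dim
        return cls(
            W_z=np.zeros((d, h)), W_r=np.zeros((d, h)), W_C=np.zeros((d, h)),
            V_z=np.zeros((h, h)), V_r=np.zeros((h, h)), V_C=np.zeros((h, h)),
            b_z=np.zeros(h), b_r=np.zeros(h), b_C=np.zeros(h),
        )


@dataclass
class GRUState:
    """One GRU step: inputs, gate activations, candidate and new hidden state."""

    x_t: np.ndarray
    h_prev: np.ndarray
    z_t: np.ndarray
    r_t: np.ndarray
    C_hat_t: np.ndarray
    h_t: np.ndarray


def gru_cell_step(x_t, h_prev, params: GRUParams) -> GRUState:
    """One GRU update.

    z_t = sigma(W_z x_t + V_z h_prev + b_z)          (update gate)
    r_t = sigma(W_r x_t + V_r h_prev + b_r)          (reset gate)
    C_hat_t = tanh(W_C x_t + V_C (r_t * h_prev) + b_C)  (candidate state)
    h_t = z_t * h_prev + (1 - z_t) * C_hat_t         (new hidden state)

    An update gate near 1 retains the old state; near 0 it adopts the
    candidate.
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    d, h = params.W_z.shape
    if x_t.shape != (d,) or h_prev.shape != (h,):
        raise ValueError(
            f"expected x_t of shape ({d},) and h_prev of shape ({h},), "
            f"got {x_t.shape} and {h_prev.shape}"
        )
    z_t = _nn.sigmoid(x_t @ params.W_z + h_prev @ params.V_z + params.b_z)
    r_t = _nn.sigmoid(x_t @ params.W_r + h_prev @ params.V_r + params.b_r)
    C_hat_t = np.tanh(x_t @ params.W_C + (r_t * h_prev) @ params.V_C + params.b_C)
    h_t = z_t * h_prev + (1.0 - z_t) * C_hat_t
    return GRUState(x_t=x_t, h_prev=h_prev, z_t=z_t, r_t=r_t, C_hat_t=C_hat_t, h_t=h_t)


# ---------------------------------------------------------------------------
# Architecture and training configuration
# ---------------------------------------------------------------------------

BACKBONE_KINDS = ("gru", "bigru", "lstm", "bilstm")


@dataclass
class BackboneConfig:
    """Architecture of the supervised feature extractor."""

    vocab_size: int
    embedding_dim: int = 32
    gru_units: int = 200
    dense_units: tuple[int, ...] = (128, 64, 32, 16)
    dropout_rate: float = 0.2
    latent_layer_index: int = 4  # 1-based into [recurrent, dense_1, ...]
    backbone_kind: str = "gru"
    input_encoding: str = "embedding"  # or "onehot"
    dropout_after_recurrent: bool = False

    def __post_init__(self) -> None:
        self.dense_units = tuple(int(u) for u in self.dense_units)
        if self.backbone_kind not in BACKBONE_KINDS:
            raise ValueError(f"backbone_kind must be one of {BACKBONE_KINDS}")
        if self.input_encoding not in ("embedding", "onehot"):
            raise ValueError("input_encoding must be 'embedding' or 'onehot'")
        if not 1 <= self.latent_layer_index <= 1 + len(self.dense_units):
            raise ValueError(
                f"latent_layer_index {self.latent_layer_index} outside "
                f"1..{1 + len(self.dense_units)}"
            )
        if self.gru_units < 1 or any(u < 1 for u in self.dense_units):
            raise ValueError("all unit counts must be >= 1")

    @property
    def latent_dim(self) -> int:
        widths = self.feature_widths
        return widths[self.latent_layer_index - 1]

    @property
    def feature_widths(self) -> tuple[int, ...]:
        recurrent = self.gru_units * (2 if self.backbone_kind.startswith("bi") else 1)
        return (recurrent,) + self.dense_units


@dataclass
class TrainConfig:
    """Optimization settings for the supervised phase.

    The defaults (binary cross-entropy, Adam at 1e-3, batch 32, at most 50
    epochs, patience 5 on validation loss with best-weight restore) are
    conventional for this architecture.
    """

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 5
    monitor: str = "val_loss"  # or "val_accuracy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.early_stopping_patience < self.epochs:
            raise ValueError("patience must satisfy 0 <= patience < epochs")
        if self.monitor not in ("val_loss", "val_accuracy"):
            raise ValueError("monitor must be val_loss or val_accuracy")


def build_backbone(config: BackboneConfig, seed: int = 0, dtype=np.float32) -> _nn.Network:
    """Instantiate the network for a given architecture config."""
    rng = np.random.default_rng(seed)
    n_tokens = config.vocab_size + 1  # id 0 is padding/unknown
    if config.input_encoding == "embedding":
        encoder = _nn.Embedding(rng, n_tokens, config.embedding_dim, dtype=dtype)
    else:
        encoder = _nn.OneHot(n_tokens, dtype=dtype)
    in_dim = encoder.dim
    cell = _nn.GRU if config.backbone_kind.endswith("gru") else _nn.LSTM
    if config.backbone_kind.startswith("bi"):
        recurrent = _nn.Bidirectional(
            cell(rng, in_dim, config.gru_units, dtype=dtype),
            cell(rng, in_dim, config.gru_units, dtype=dtype),
        )
    else:
        recurrent = cell(rng, in_dim, config.gru_units, dtype=dtype)
    width = recurrent.units
    blocks = []
    for units in config.dense_units:
        dense = _nn.Dense(rng, width, units, activation="relu", dtype=dtype)
        drop = _nn.Dropout(config.dropout_rate) if config.dropout_rate > 0 else None
        blocks.append((dense, drop))
        width = units
    head = _nn.Dense(rng, width, 1, activation="linear", dtype=dtype)
    post_drop = (
        _nn.Dropout(config.dropout_rate)
        if config.dropout_after_recurrent and config.dropout_rate > 0
        else None
    )
    return _nn.Network(encoder, recurrent, blocks, head, dtype=dtype,
                       post_recurrent_drop=post_drop)


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement; keep the best epoch."""

    def __init__(self, patience: int, mode: str = "min"):
        self.patience = patience
        self.sign = 1.0 if mode == "min" else -1.0
        self.best: Optional[float] = None
        self.best_epoch: Optional[int] = None
        self.wait = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record an epoch's monitored value; return True on improvement."""
        if self.best is None or self.sign * value < self.sign * self.best:
            self.best = value
            self.best_epoch = epoch
            self.wait = 0
            return True
        self.wait += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.wait >= self.patience


def _evaluate(net: _nn.Network, tokens, lengths, y, batch_size: int = 512):
    proba = net.predict_proba(tokens, lengths, batch_size=batch_size)
    eps = np.finfo(np.float64).tiny
    p = np.clip(proba.astype(np.float64), eps, 1.0 - 1e-12)
    loss = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
    acc = float(np.mean((proba >= 0.5).astype(int) == y))
    return loss, acc


def train_supervised(
    net: _nn.Network,
    train: TokenizedDataset,
    val: TokenizedDataset,
    config: TrainConfig,
) -> pd.DataFrame:
    """Train in place; return the per-epoch history.

    Minimizes binary cross-entropy with Adam; training stops once the
    monitored validation quantity fails to improve for
    ``early_stopping_patience`` consecutive epochs, and the best epoch's
    weights are restored.  History columns: epoch, loss, accuracy, val_loss,
    val_accuracy.
    """
    for name, ds in (("train", train), ("validation", val)):
        if ds.labels is None:
            raise ValueError(f"{name} dataset is unlabelled")
    y_train = train.labels.astype(np.float64)
    y_val = val.labels.astype(np.float64)
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(lr=config.learning_rate)
    stopper = EarlyStopping(
        config.early_stopping_patience,
        mode="min" if config.monitor == "val_loss" else "max",
    )
    best_weights = net.get_weights()
    rows = []
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(train))
        loss_sum = 0.0
        correct = 0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = net.forward(train.tokens[idx], train.lengths[idx], train=True, rng=rng)
            loss, dlogits = _nn.bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            net.zero_grad()
            net.backward(dlogits)
            opt.step(net.weights, net.grads)
            loss_sum += loss * len(idx)
            correct += int(np.sum((logits >= 0.0).astype(int) == y_train[idx]))
        val_loss, val_acc = _evaluate(net, val.tokens, val.lengths, y_val)
        rows.append(
            {
                "epoch": epoch,
                "loss": loss_sum / len(perm),
                "accuracy": correct / len(perm),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        monitored = val_loss if config.monitor == "val_loss" else val_acc
        if stopper.update(monitored, epoch):
            best_weights = net.get_weights()
        if stopper.should_stop:
            break
    net.set_weights(best_weights)
    return pd.DataFrame(rows)


def extract_latent(net: _nn.Network, data: TokenizedDataset, layer_index: int = 4) -> np.ndarray:
    """Latent matrix (n x d) from the configured feature layer, eval mode."""
    return np.asarray(net.latent(data.tokens, data.lengths, layer_index))


# ---------------------------------------------------------------------------
# Scikit-learn estimator
# ---------------------------------------------------------------------------

class RecurrentNetClassifier(ClassifierMixin, BaseEstimator):
    """Recurrent binary sequence classifier over padded token matrices.

    ``fit`` expects an integer token matrix (rows post-padded with 0) and
    0/1 labels; an internal stratified validation split drives early
    stopping unless ``validation_data`` is passed.  ``transform`` returns
    the latent representation of the configured feature layer.
    """

    def __init__(self, gru_units: int = 200, dense_units: tuple[int, ...] = (128, 64, 32, 16),
                 embedding_dim: int = 32, dropout_rate: float = 0.2,
                 latent_layer_index: int = 4, backbone_kind: str = "gru",
                 input_encoding: str = "embedding", dropout_after_recurrent: bool = False,
                 epochs: int = 50, batch_size: int = 32, learning_rate: float = 1e-3,
                 early_stopping_patience: int = 5, monitor: str = "val_loss",
                 validation_fraction: float = 0.2, random_state: int = 0):
        self.gru_units = gru_units
        self.dense_units = dense_units
        self.embedding_dim = embedding_dim
        self.dropout_rate = dropout_rate
        self.latent_layer_index = latent_layer_index
        self.backbone_kind = backbone_kind
        self.input_encoding = input_encoding
        self.dropout_after_recurrent = dropout_after_recurrent
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.early_stopping_patience = early_stopping_patience
        self.monitor = monitor
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    @staticmethod
    def _lengths(X: np.ndarray, lengths) -> np.ndarray:
        if lengths is not None:
            return np.asarray(lengths, dtype=np.int64)
        # true length = position after the last nonzero token (post-padding)
        nonzero = X != 0
        return np.where(
            nonzero.any(axis=1), X.shape[1] - np.argmax(nonzero[:, ::-1], axis=1), 0
        ).astype(np.int64)

    def _as_dataset(self, X, y=None, lengths=None) -> TokenizedDataset:
        if isinstance(X, TokenizedDataset):
            return X
        X = np.asarray(X, dtype=np.int32)
        vocab = Vocabulary(
            k=1, index_of={}, ordering="custom"
        ) if not hasattr(self, "_vocab_stub") else self._vocab_stub
        return TokenizedDataset(
            tokens=X,
            lengths=self._lengths(X, lengths),
            labels=None if y is None else np.asarray(y, dtype=np.int8),
            vocab=vocab,
        )

    def fit(self, X, y=None, lengths=None, validation_data=None) -> "RecurrentNetClassifier":
        data = self._as_dataset(X, y, lengths)
        if data.labels is None:
            raise ValueError("fit requires labels")
        vocab_size = int(data.tokens.max()) if data.tokens.size else 0
        self.config_ = BackboneConfig(
            vocab_size=vocab_size,
            embedding_dim=self.embedding_dim,
            gru_units=self.gru_units,
            dense_units=tuple(self.dense_units),
            dropout_rate=self.dropout_rate,
            latent_layer_index=self.latent_layer_index,
            backbone_kind=self.backbone_kind,
            input_encoding=self.input_encoding,
            dropout_after_recurrent=self.dropout_after_recurrent,
        )
        train_cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stopping_patience=self.early_stopping_patience,
            monitor=self.monitor,
            seed=self.random_state,
        )
        if validation_data is None:
            train_ds, val_ds = _stratified_val_split(
                data, self.validation_fraction, self.random_state
            )
        else:
            train_ds = data
            val_ds = self._as_dataset(*validation_data) if isinstance(
                validation_data, tuple
            ) else validation_data
        self.network_ = build_backbone(self.config_, seed=self.random_state)
        self.history_ = train_supervised(self.network_, train_ds, val_ds, train_cfg)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = data.tokens.shape[1]
        return self

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        check_is_fitted(self, "network_")
        data = self._as_dataset(X, lengths=lengths)
        p1 = self.network_.predict_proba(data.tokens, data.lengths)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, lengths=None) -> np.ndarray:
        return (self.predict_proba(X, lengths=lengths)[:, 1] >= 0.5).astype(np.int64)

    def transform(self, X, lengths=None) -> np.ndarray:
        """Latent representation of the configured feature layer."""
        check_is_fitted(self, "network_")
        data = self._as_dataset(X, lengths=lengths)
        return self.network_.latent(data.tokens, data.lengths, self.latent_layer_index)

    # -- persistence -------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        check_is_fitted(self, "network_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz",
                 **{f"w{i}": w for i, w in enumerate(self.network_.weights)})
        meta = {"params": self.get_params(), "config": asdict(self.config_)}
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        self.history_.to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "RecurrentNetClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        params = meta["params"]
        params["dense_units"] = tuple(params["dense_units"])
        est = cls(**params)
        cfg = meta["config"]
        cfg["dense_units"] = tuple(cfg["dense_units"])
        est.config_ = BackboneConfig(**cfg)
        est.network_ = build_backbone(est.config_, seed=est.random_state)
        data = np.load(directory / "weights.npz")
        est.network_.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        est.history_ = pd.read_csv(directory / "history.csv")
        est.classes_ = np.array([0, 1])
        return est


def _stratified_val_split(data: TokenizedDataset, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    y = data.labels
    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(len(idx) * fraction)))
        val_idx.extend(idx[rng.permutation(len(idx))[:n_val]])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True

    def subset(mask):
        return TokenizedDataset(
            tokens=data.tokens[mask],
            lengths=data.lengths[mask],
            labels=y[mask],
            vocab=data.vocab,
            ids=[data.ids[i] for i in np.flatnonzero(mask)] if data.ids else [],
        )

    return subset(~val_mask), subset(val_mask)
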
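"""The per-window classifier: a lightweight bidirectional recurrent net.

Architecture (defaults): a 26-token embedding of dimension 8, a
bidirectional LSTM with 8 units per direction whose two final states are
concatenated, a unidirectional LSTM with 4 units refining that
16-dimensional summary, and a single sigmoid output unit. Dropout (10%)
follows the embedding, the bidirectional layer, and the unidirectional
layer. With these defaults the network has exactly 1,637 trainable
parameters; :func:`count_trainable_params` states the closed form and
the built model must report the same total — this is an architectural
contract, not an estimate.

Training: binary cross-entropy, Adam at learning rate 1e-3, batch size
32, 30 epochs, in a 6-fold cross-validation whose fold models are later
combined by probability averaging (see :mod:`asmscan.scanner`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import Adam, bce_from_logits, lstm_backward, lstm_forward, sigmoid

WINDOW_LEN = 40


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the per-window classifier."""

    vocab_size: int = 26
    embed_dim: int = 8
    bi_units: int = 8  # per direction
    uni_units: int = 4
    dropout: float = 0.10
    window_len: int = WINDOW_LEN

    def __post_init__(self) -> None:
        for name in ("vocab_size", "embed_dim", "bi_units", "uni_units", "window_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    seed: int = 0
    neg_per_pos: float | str = "all"
    resample_pads_per_epoch: bool = False
    checkpoint_best: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.neg_per_pos != "all" and float(self.neg_per_pos) <= 0:
            raise ValueError("neg_per_pos must be positive or 'all'")


def count_trainable_params(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count of the architecture.

    Embedding V*d; each LSTM direction 4*u1*(d+u1+1) (single bias per
    gate); unidirectional LSTM 4*u2*(2*u1+u2+1); output u2+1.
    """
    v, d = config.vocab_size, config.embed_dim
    u1, u2 = config.bi_units, config.uni_units
    return (
        v * d
        + 2 * (4 * u1 * (d + u1 + 1))
        + 4 * u2 * (2 * u1 + u2 + 1)
        + (u2 + 1)
    )


class BiLSTMClassifier:
    """The per-window model, with explicit parameter arrays.

    Use :func:`build_model` to construct one with seeded initialization.
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # -- construction -------------------------------------------------

    @classmethod
    def initialize(cls, config: ModelConfig, seed: int = 0) -> "BiLSTMClassifier":
        rng = np.random.default_rng(seed)
        d, u1, u2 = config.embed_dim, config.bi_units, config.uni_units
        params = {
            "E": rng.uniform(-0.05, 0.05, size=(config.vocab_size, d)),
            "Wf": _nn.glorot_uniform(rng, (d, 4 * u1)),
            "Uf": _nn.orthogonal(rng, (u1, 4 * u1)),
            "bf": _nn.lstm_bias(u1),
            "Wb": _nn.glorot_uniform(rng, (d, 4 * u1)),
            "Ub": _nn.orthogonal(rng, (u1, 4 * u1)),
            "bb": _nn.lstm_bias(u1),
            "W2": _nn.glorot_uniform(rng, (2 * u1, 4 * u2)),
            "U2": _nn.orthogonal(rng, (u2, 4 * u2)),
            "b2": _nn.lstm_bias(u2),
            "w_out": _nn.glorot_uniform(rng, (u2, 1)),
            "b_out": np.zeros(1),
        }
        return cls(config, params)

    @property
    def n_params(self) -> int:
        """Trainable-parameter total reported from the actual arrays."""
        return int(sum(p.size for p in self.params.values()))

    # -- forward ------------------------------------------------------

    def _check_tokens(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        if tokens.shape[1] != self.config.window_len:
            raise ValueError(
                f"windows must have length {self.config.window_len}, "
                f"got {tokens.shape[1]}"
            )
        return tokens

    def _forward(self, tokens: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass. With ``rng`` set, dropout is active (training);
        otherwise inference mode. Returns (logits, penultimate, cache)."""
        p = self.params
        u2 = self.config.uni_units
        drop = self.config.dropout
        train = rng is not None
        use_drop = train and drop > 0.0

        X = p["E"][tokens]
        masks = {}
        if use_drop:
            masks["m1"] = (rng.random(X.shape) >= drop) / (1.0 - drop)
            X = X * masks["m1"]
        hf, cache_f = lstm_forward(X, p["Wf"], p["Uf"], p["bf"], want_cache=train)
        hb, cache_b = lstm_forward(
            X[:, ::-1], p["Wb"], p["Ub"], p["bb"], want_cache=train
        )
        hcat = np.concatenate([hf, hb], axis=1)
        x2 = hcat
        if use_drop:
            masks["m2"] = (rng.random(x2.shape) >= drop) / (1.0 - drop)
            x2 = x2 * masks["m2"]
        # unidirectional layer sees the length-1 sequence of the summary
        # vector; with zero initial state its recurrent kernel U2 is inert
        # in the forward pass but remains a counted trainable parameter.
        z2 = x2 @ p["W2"] + p["b2"]
        i2 = sigmoid(z2[:, :u2])
        f2 = sigmoid(z2[:, u2 : 2 * u2])
        g2 = np.tanh(z2[:, 2 * u2 : 3 * u2])
        o2 = sigmoid(z2[:, 3 * u2 :])
        c2 = i2 * g2
        tc2 = np.tanh(c2)
        h2 = o2 * tc2
        h2d = h2
        if use_drop:
            masks["m3"] = (rng.random(h2.shape) >= drop) / (1.0 - drop)
            h2d = h2 * masks["m3"]
        logits = (h2d @ p["w_out"] + p["b_out"]).ravel()
        cache = None
        if train:
            cache = (tokens, X, cache_f, cache_b, x2, i2, f2, g2, o2, tc2, h2d, masks)
        return logits, h2, cache

    def predict_proba(self, tokens: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Per-window probabilities in (0, 1), inference mode (no dropout)."""
        tokens = self._check_tokens(tokens)
        out = np.empty(len(tokens))
        for lo in range(0, len(tokens), batch_size):
            logits, _, _ = self._forward(tokens[lo : lo + batch_size])
            out[lo : lo + batch_size] = sigmoid(logits)
        return out

    def penultimate(self, tokens: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Final-state output of the unidirectional layer (n, uni_units)."""
        tokens = self._check_tokens(tokens)
        out = np.empty((len(tokens), self.config.uni_units))
        for lo in range(0, len(tokens), batch_size):
            _, h2, _ = self._forward(tokens[lo : lo + batch_size])
            out[lo : lo + batch_size] = h2
        return out

    # -- backward -----------------------------------------------------

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        u2 = self.config.uni_units
        tokens, X, cache_f, cache_b, x2, i2, f2, g2, o2, tc2, h2d, masks = cache
        dlogits = dlogits[:, None]
        grads = {
            "w_out": h2d.T @ dlogits,
            "b_out": dlogits.sum(axis=0),
        }
        dh2 = (dlogits @ p["w_out"].T) * masks.get("m3", 1.0)
        # single LSTM step backward (c_prev = 0, h_prev = 0)
        do2 = dh2 * tc2
        dc2 = dh2 * o2 * (1.0 - tc2 * tc2)
        di2 = dc2 * g2
        dg2 = dc2 * i2
        dz2 = np.concatenate(
            [
                di2 * i2 * (1.0 - i2),
                np.zeros_like(f2),  # forget gate: c_prev = 0
                dg2 * (1.0 - g2 * g2),
                do2 * o2 * (1.0 - o2),
            ],
            axis=1,
        )
        grads["W2"] = x2.T @ dz2
        grads["U2"] = np.zeros_like(p["U2"])  # h_prev = 0, length-1 input
        grads["b2"] = dz2.sum(axis=0)
        dhcat = (dz2 @ p["W2"].T) * masks.get("m2", 1.0)
        u1 = self.config.bi_units
        dXf, grads["Wf"], grads["Uf"], grads["bf"] = lstm_backward(
            dhcat[:, :u1], p["Wf"], p["Uf"], cache_f
        )
        dXb, grads["Wb"], grads["Ub"], grads["bb"] = lstm_backward(
            dhcat[:, u1:], p["Wb"], p["Ub"], cache_b
        )
        dX = (dXf + dXb[:, ::-1]) * masks.get("m1", 1.0)
        dE = np.zeros_like(p["E"])
        np.add.at(dE, tokens.ravel(), dX.reshape(-1, X.shape[2]))
        grads["E"] = dE
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path: str | Path, config: ModelConfig) -> "BiLSTMClassifier":
        with np.load(path) as data:
            params = {k: data[k] for k in data.files}
        model = cls(config, params)
        if model.n_params != count_trainable_params(config):
            raise ValueError("checkpoint does not match the model configuration")
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> BiLSTMClassifier:
    """Build the classifier with seeded random initialization.

    The built model's reported parameter total always equals
    :func:`count_trainable_params` of its configuration.
    """
    config = config or ModelConfig()
    model = BiLSTMClassifier.initialize(config, seed=seed)
    expected = count_trainable_params(config)
    assert model.n_params == expected, (model.n_params, expected)
    return model


def cv_split(
    positives: Sequence, negatives: Sequence, k: int = 6, seed: int = 0
) -> list[tuple[list, list]]:
    """Stratified k-fold split of positive and negative ids.

    Each class is shuffled and partitioned into k near-equal blocks
    (sizes differ by at most 1); fold i validates on block i of each
    class and trains on the rest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(positives) < k or len(negatives) < k:
        raise ValueError(f"need at least k={k} items of each class")
    rng = np.random.default_rng(seed)
    folds = []
    blocks = {}
    for name, items in (("pos", list(positives)), ("neg", list(negatives))):
        order = rng.permutation(len(items))
        blocks[name] = [
            [items[j] for j in part] for part in np.array_split(order, k)
        ]
    for i in range(k):
        val = blocks["pos"][i] + blocks["neg"][i]
        train = [
            x for j in range(k) if j != i for x in blocks["pos"][j] + blocks["neg"][j]
        ]
        folds.append((train, val))
    return folds


@dataclass
class FoldModel:
    """One trained cross-validation fold."""

    fold_index: int
    model: BiLSTMClassifier
    train_ids: list = field(default_factory=list)
    val_ids: list = field(default_factory=list)
    val_metrics: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)

    def predict_proba(self, tokens: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(tokens)


def train_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    fold_index: int = 0,
    train_ids: list | None = None,
    val_ids: list | None = None,
    repad=None,
) -> FoldModel:
    """Train one fold model with Adam on binary cross-entropy.

    Runs exactly ``train_config.epochs`` epochs (no early stopping),
    recording per-epoch training and validation loss. Fully reproducible
    from ``train_config.seed`` and ``fold_index``. ``repad``, if given,
    is called as ``repad(rng)`` at each epoch start and must return a
    freshly prepadded copy of the full training matrix (per-epoch pad
    resampling).
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    X_train = np.asarray(X_train, dtype=np.int64)
    X_val = np.asarray(X_val, dtype=np.int64)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if X_train.shape[1] != model_config.window_len:
        raise ValueError(f"training windows must have length {model_config.window_len}")
    classes = set(np.unique(y_train))
    if classes != {0.0, 1.0}:
        raise ValueError("training data must contain both classes (labels 0 and 1)")

    ss = np.random.SeedSequence([train_config.seed, fold_index])
    init_seed, loop_seed = ss.spawn(2)
    model = build_model(model_config, seed=int(init_seed.generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(loop_seed)

    # optional negative subsampling for desk-scale runs
    keep = None
    if train_config.neg_per_pos != "all":
        pos_idx = np.flatnonzero(y_train == 1)
        neg_idx = np.flatnonzero(y_train == 0)
        n_keep = min(len(neg_idx), int(round(float(train_config.neg_per_pos) * len(pos_idx))))
        keep = np.concatenate([pos_idx, rng.choice(neg_idx, size=n_keep, replace=False)])
        X_train, y_train = X_train[keep], y_train[keep]

    opt = Adam(model.params, lr=train_config.learning_rate)
    n = len(X_train)
    bs = train_config.batch_size
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None

    for _epoch in range(train_config.epochs):
        if repad is not None:
            full = np.asarray(repad(rng), dtype=np.int64)
            X_train = full[keep] if keep is not None else full
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, bs):
            sel = perm[lo : lo + bs]
            xb, yb = X_train[sel], y_train[sel]
            logits, _, cache = model._forward(xb, rng=rng)
            loss = bce_from_logits(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {_epoch}")
            epoch_loss += loss * len(sel)
            dlogits = (sigmoid(logits) - yb) / len(sel)
            grads = model._backward(dlogits, cache)
            opt.step(grads)
        history["train_loss"].append(epoch_loss / n)
        val_logits = _predict_logits(model, X_val)
        vloss = bce_from_logits(val_logits, y_val)
        history["val_loss"].append(vloss)
        if train_config.checkpoint_best and vloss < best_val:
            best_val = vloss
            best_params = model.copy_params()

    if train_config.checkpoint_best and best_params is not None:
        model.params.update(best_params)

    val_probs = sigmoid(_predict_logits(model, X_val))
    val_metrics = {"val_loss": history["val_loss"][-1]}
    if len(set(y_val.tolist())) == 2:
        from .metrics import ScoredLabelSet, auroc, average_precision

        data = ScoredLabelSet(val_probs.tolist(), y_val.astype(int).tolist())
        val_metrics["val_auroc"] = auroc(data)
        val_metrics["val_ap"] = average_precision(data)
    return FoldModel(
        fold_index=fold_index,
        model=model,
        train_ids=list(train_ids or []),
        val_ids=list(val_ids or []),
        val_metrics=val_metrics,
        history=history,
    )


def _predict_logits(model: BiLSTMClassifier, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
    out = np.empty(len(X))
    for lo in range(0, len(X), batch_size):
        logits, _, _ = model._forward(X[lo : lo + batch_size])
        out[lo : lo + batch_size] = logits
    return out
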
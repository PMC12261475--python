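"""Minimal NumPy neural-network primitives for the window classifier.

Implements exactly what the per-window model needs: an embedding lookup,
single-bias LSTM layers (gate order input, forget, candidate, output;
one bias per gate), inverted dropout, backpropagation through time from
a final-state gradient, and the Adam optimizer. Everything is plain
float64 NumPy; with a fixed seed the computation is bit-reproducible on
a single thread.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable."""
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return q[:rows, :cols]


def lstm_bias(units: int) -> np.ndarray:
    """Zero bias with the forget gate initialized to 1."""
    b = np.zeros(4 * units)
    b[units : 2 * units] = 1.0
    return b


def lstm_forward(
    X: np.ndarray, W: np.ndarray, U: np.ndarray, b: np.ndarray,
    want_cache: bool = False,
):
    """Run an LSTM over ``X`` (B, T, d); return the final hidden state.

    When ``want_cache`` is true, per-step intermediates are kept for
    :func:`lstm_backward`.
    """
    B, T, _ = X.shape
    u = U.shape[0]
    h = np.zeros((B, u))
    c = np.zeros((B, u))
    cache = [] if want_cache else None
    for t in range(T):
        z = X[:, t] @ W + h @ U + b
        i = sigmoid(z[:, :u])
        f = sigmoid(z[:, u : 2 * u])
        g = np.tanh(z[:, 2 * u : 3 * u])
        o = sigmoid(z[:, 3 * u :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        if want_cache:
            cache.append((X[:, t], h, c, i, f, g, o, tc))
        h = o * tc
        c = c_new
    return h, cache


def lstm_backward(
    dh_last: np.ndarray, W: np.ndarray, U: np.ndarray, cache: list,
):
    """Backpropagate a gradient w.r.t. the final hidden state.

    Returns gradients for the input sequence and the three parameter
    tensors. Only the final state feeds the rest of the network, so the
    incoming gradient is a single (B, u) array.
    """
    u = U.shape[0]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * u)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    dX = []
    for t in range(len(cache) - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, tc = cache[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX.append(dz @ W.T)
        dh = dz @ U.T
        dc = dc * f
    dX.reverse()
    return np.stack(dX, axis=1), dW, dU, db


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )
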
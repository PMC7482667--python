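"""Three-layer perceptron trained by online backpropagation.

A parsimonious feed-forward network — one hidden layer (default 2 units),
sigmoid activations at hidden and output layers — trained on squared error
with per-sample (online) updates and momentum.  The sample order is
reshuffled every epoch.  All randomness (weight initialization, shuffles)
comes from a caller-supplied generator, so training is bitwise
deterministic under a seed.

The inner loop is JIT-compiled with numba; the arithmetic is plain float64
and independent of threading, so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass
class Hyperparams:
    """Training hyper-parameters.

    ``n_hidden`` defaults to 2, the parsimonious-architecture convention;
    ``init_scale`` bounds the uniform weight initialization."""

    n_hidden: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.5
    epochs: int = 300
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")


@dataclass
class MLPWeights:
    """Weights of one trained perceptron.

    ``w_in_hidden`` is (n_inputs, n_hidden); ``b_hidden`` and
    ``w_hidden_out`` are length n_hidden; ``b_out`` is scalar."""

    w_in_hidden: np.ndarray
    b_hidden: np.ndarray
    w_hidden_out: np.ndarray
    b_out: float

    def __post_init__(self) -> None:
        self.w_in_hidden = np.asarray(self.w_in_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_hidden_out = np.asarray(self.w_hidden_out, dtype=float)
        n_in, n_h = self.w_in_hidden.shape
        if self.b_hidden.shape != (n_h,) or self.w_hidden_out.shape != (n_h,):
            raise ValueError("inconsistent MLP weight dimensions")
        if not (
            np.all(np.isfinite(self.w_in_hidden))
            and np.all(np.isfinite(self.b_hidden))
            and np.all(np.isfinite(self.w_hidden_out))
            and np.isfinite(self.b_out)
        ):
            raise ValueError("non-finite MLP weights")


@njit(cache=True)
def _train_kernel(X, y, W1, b1, w2, b2, perms, lr, mom):  # pragma: no cover
    n_in = X.shape[1]
    n_h = W1.shape[1]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = 0.0
    h = np.empty(n_h)
    d_h = np.empty(n_h)
    for e in range(perms.shape[0]):
        for s in range(perms.shape[1]):
            idx = perms[e, s]
            # forward pass
            for j in range(n_h):
                a = b1[j]
                for i in range(n_in):
                    a += X[idx, i] * W1[i, j]
                h[j] = 1.0 / (1.0 + np.exp(-a))
            o = b2[0]
            for j in range(n_h):
                o += h[j] * w2[j]
            o = 1.0 / (1.0 + np.exp(-o))
            # backward pass: squared error E = (o - y)^2 / 2
            d_o = (o - y[idx]) * o * (1.0 - o)
            for j in range(n_h):
                d_h[j] = d_o * w2[j] * h[j] * (1.0 - h[j])
            # momentum updates
            vb2 = mom * vb2 - lr * d_o
            b2[0] += vb2
            for j in range(n_h):
                vw2[j] = mom * vw2[j] - lr * d_o * h[j]
                w2[j] += vw2[j]
                vb1[j] = mom * vb1[j] - lr * d_h[j]
                b1[j] += vb1[j]
                for i in range(n_in):
                    vW1[i, j] = mom * vW1[i, j] - lr * d_h[j] * X[idx, i]
                    W1[i, j] += vW1[i, j]


def train_mlp_rng(
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> MLPWeights:
    """Train with randomness drawn from ``rng`` (init weights, then one
    permutation per epoch, in that fixed order)."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x inputs)")
    n_samples, n_in = X.shape
    if n_samples == 0:
        raise ValueError("empty training set")
    if y.shape != (n_samples,):
        raise ValueError(f"y must have shape ({n_samples},), got {y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (complete)")
    s = hyper.init_scale
    W1 = rng.uniform(-s, s, size=(n_in, hyper.n_hidden))
    b1 = rng.uniform(-s, s, size=hyper.n_hidden)
    w2 = rng.uniform(-s, s, size=hyper.n_hidden)
    b2 = np.array([rng.uniform(-s, s)])
    perms = rng.permuted(
        np.broadcast_to(np.arange(n_samples), (hyper.epochs, n_samples)), axis=1
    ).astype(np.int64)
    _train_kernel(
        X, y, W1, b1, w2, b2, perms,
        float(hyper.learning_rate), float(hyper.momentum),
    )
    return MLPWeights(W1, b1, w2, float(b2[0]))


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyperparams | None = None,
    seed: int = 0,
) -> MLPWeights:
    """Train a 3-layer perceptron; deterministic under (hyper, seed).

    With ``epochs=0`` the returned weights equal the seeded random
    initialization."""
    return train_mlp_rng(X, y, hyper or Hyperparams(), np.random.default_rng(seed))


def predict_mlp(weights: MLPWeights, X: np.ndarray) -> np.ndarray:
    """Forward pass: sigmoid(hidden) then sigmoid(output), values in (0, 1)."""
    X = np.asarray(X, dtype=float)
    h = 1.0 / (1.0 + np.exp(-(X @ weights.w_in_hidden + weights.b_hidden)))
    o = 1.0 / (1.0 + np.exp(-(h @ weights.w_hidden_out + weights.b_out)))
    return o


def summed_weight_scores(weights: MLPWeights) -> np.ndarray:
    """Signed input->output interaction score per input.

    score(i) = sum_h w_in_hidden[i, h] * w_hidden_out[h]: the summed
    connection weights leading from input i through the hidden layer to
    the output."""
    return weights.w_in_hidden @ weights.w_hidden_out
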
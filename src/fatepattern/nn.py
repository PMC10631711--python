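"""Minimal NumPy neural-network core: layers, losses and Adam.

Implements exactly the primitives the two models need — the graph
convolution Z' = D^(-1/2) A D^(-1/2) X W1 + X W2 + b with a skip transform,
global attention-sum pooling over a disjoint-union batch, dense layers and a
softmax classifier — with hand-written gradients.  Everything is seeded and
runs in float32 on the CPU.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "glorot",
    "normalized_adjacency",
    "gcs_dense_oracle",
    "segment_softmax",
    "segment_sum",
    "Adam",
    "SoftmaxMLP",
]

DTYPE = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def activation(name: str, P: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(P, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-P))
    if name == "linear":
        return P
    raise ValueError(f"unknown activation {name!r}")


def activation_grad(name: str, P: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """d(activation)/dP given pre-activation P and output Z."""
    if name == "relu":
        return (P > 0).astype(P.dtype)
    if name == "sigmoid":
        return Z * (1.0 - Z)
    if name == "linear":
        return np.ones_like(P)
    raise ValueError(f"unknown activation {name!r}")


def normalized_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetrically normalized adjacency D^(-1/2) A D^(-1/2).

    Degrees are row sums of (possibly weighted) A; degree-0 nodes get a zero
    normalization entry, so isolated nodes pass nothing through the
    aggregation term.
    """
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    D = sp.diags(inv_sqrt)
    return (D @ A @ D).tocsr().astype(DTYPE)


def gcs_dense_oracle(A: np.ndarray, X: np.ndarray, W1: np.ndarray,
                     W2: np.ndarray, b: np.ndarray, act: str = "linear") -> np.ndarray:
    """Straightforward dense evaluation of the graph-convolution-with-skip
    equation, used as an independent check of the sparse implementation."""
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    Ahat = d_inv[:, None] * A * d_inv[None, :]
    return activation(act, Ahat @ X @ W1 + X @ W2 + b)


def segment_sum(values: np.ndarray, index: np.ndarray, n_segments: int) -> np.ndarray:
    out = np.zeros((n_segments,) + values.shape[1:], dtype=values.dtype)
    np.add.at(out, index, values)
    return out


def segment_softmax(scores: np.ndarray, index: np.ndarray, n_segments: int) -> np.ndarray:
    """Softmax of node scores within each graph of a disjoint-union batch."""
    maxes = np.full(n_segments, -np.inf, dtype=scores.dtype)
    np.maximum.at(maxes, index, scores)
    e = np.exp(scores - maxes[index])
    denom = segment_sum(e, index, n_segments)
    return e / denom[index]


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            self.params[k] -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class SoftmaxMLP:
    """Fully connected ReLU network with a softmax output layer, trained by
    Adam on sparse (integer-label) categorical cross-entropy."""

    def __init__(self, in_dim: int, n_classes: int, hidden=(64, 64, 64),
                 lr: float = 1e-3, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [in_dim, *hidden, n_classes]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            self.params[f"W{i}"] = glorot(rng, (dims[i], dims[i + 1]))
            self.params[f"b{i}"] = np.zeros(dims[i + 1], dtype=DTYPE)
        self.n_layers = len(dims) - 1
        self.n_classes = n_classes
        self.opt = Adam(self.params, lr=lr)
        self.history: list[dict] = []

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray):
        acts = [X.astype(DTYPE)]
        pre = []
        H = acts[0]
        for i in range(self.n_layers):
            P = H @ self.params[f"W{i}"] + self.params[f"b{i}"]
            pre.append(P)
            H = np.maximum(P, 0.0) if i < self.n_layers - 1 else P
            acts.append(H)
        logits = acts[-1]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        return acts, pre, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[2]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(X)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # -- training ----------------------------------------------------------
    def _backward(self, acts, pre, probs, y) -> dict[str, np.ndarray]:
        n = len(y)
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads = {}
        for i in range(self.n_layers - 1, -1, -1):
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.params[f"W{i}"].T) * (pre[i - 1] > 0)
        return grads

    def fit(self, X, y, X_val, y_val, batch_size: int = 128,
            max_epochs: int = 500, patience: int = 75, seed: int = 0,
            min_epochs: int = 0) -> "SoftmaxMLP":
        """Train with an autostop on the validation loss: after ``patience``
        epochs without improvement training stops and the best checkpoint is
        restored."""
        X = np.asarray(X, dtype=DTYPE)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(seed)
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        since_best = 0
        for epoch in range(max_epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), batch_size):
                sel = order[start:start + batch_size]
                acts, pre, probs = self._forward(X[sel])
                self.opt.step(self._backward(acts, pre, probs, y[sel]))
            val_loss = self.loss(X_val, y_val)
            self.history.append({"epoch": epoch, "val_loss": val_loss})
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience and epoch + 1 >= min_epochs:
                    break
        self.params.update(best_params)
        return self
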
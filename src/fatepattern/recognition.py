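"""Graph-neural-network regression of the dispersion parameter q.

The recognizer reads a whole cell graph (binary fates as node features,
normalized-distance edge weights) and outputs one value in (0, 1).  Its
architecture is two graph-convolution-with-skip layers,

    Z' = act( D^(-1/2) A D^(-1/2) X W1 + X W2 + b ),

with 450 (relu) and 150 (sigmoid) channels, a global attention-sum pooling
layer (per-graph softmax attention over nodes), and a dense head ending in a
single sigmoid unit.  Training minimizes the mean squared error against the
simulated q labels with Adam (starting learning rate 1e-4) and an adaptive
schedule that lowers the rate by a factor of 0.2 after ten epochs without
validation improvement.  Batches of graphs are handled as disjoint unions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from fatepattern.cellgraph import CellGraph, GraphBatch, disjoint_union
from fatepattern import nn

__all__ = [
    "GCSLayer",
    "RecogTrainConfig",
    "RecogEvalReport",
    "RecognizerModel",
    "gcs_forward",
    "attn_sum_pool",
    "train_recognizer",
    "predict_q",
    "hyperparameter_grid",
]


@dataclass
class GCSLayer:
    """One graph convolution with skip: weights for the aggregation term
    (W1), the skip term (W2), a bias and an activation."""

    W1: np.ndarray
    W2: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    @property
    def channels(self) -> int:
        return self.W1.shape[1]


def gcs_forward(layer: GCSLayer, X: np.ndarray, A, D=None) -> np.ndarray:
    """Apply one graph-convolution-with-skip layer.

    ``A`` may be dense or sparse; degrees are taken from ``D`` (diagonal
    matrix or vector) when given, else computed as row sums of A.  Isolated
    nodes receive a zero normalization entry, so only the skip term acts on
    them.
    """
    A = sp.csr_matrix(A)
    if D is None:
        deg = np.asarray(A.sum(axis=1)).ravel()
    else:
        D = np.asarray(D)
        deg = np.diag(D) if D.ndim == 2 else D.ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    Ahat = sp.diags(inv_sqrt) @ A @ sp.diags(inv_sqrt)
    P = Ahat @ (X @ layer.W1) + X @ layer.W2 + layer.b
    return nn.activation(layer.activation, P)


def attn_sum_pool(X: np.ndarray, attn: np.ndarray, graph_index: np.ndarray,
                  n_graphs: int | None = None) -> np.ndarray:
    """Global attention-sum pooling: per-graph softmax of node scores
    X @ attn, then the attention-weighted sum of node features."""
    graph_index = np.asarray(graph_index)
    if n_graphs is None:
        n_graphs = int(graph_index.max()) + 1
    counts = np.bincount(graph_index, minlength=n_graphs)
    if np.any(counts == 0):
        raise ValueError("every graph in the batch needs at least one node")
    scores = X @ attn
    alpha = nn.segment_softmax(scores, graph_index, n_graphs)
    return nn.segment_sum(alpha[:, None] * X, graph_index, n_graphs)


@dataclass(frozen=True)
class RecogTrainConfig:
    channels: tuple[int, int] = (450, 150)
    activations: tuple[str, str] = ("relu", "sigmoid")
    dense_head: tuple[int, ...] = (50,)  # hidden widths before the 1-unit output
    lr: float = 1e-4
    plateau_factor: float = 0.2
    plateau_patience: int = 10
    early_stop_patience: int = 30
    max_epochs: int = 300
    batch_size: int = 32
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    weighted_adjacency: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class RecogEvalReport:
    mse: float
    max_error: float
    frac_below_005: float
    true_q: np.ndarray
    pred_q: np.ndarray
    history: list = field(default_factory=list)


class RecognizerModel:
    """Two GCS layers + attention-sum pooling + dense head with sigmoid
    output, all parameters in one flat dict."""

    def __init__(self, cfg: RecogTrainConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2 = cfg.channels
        p: dict[str, np.ndarray] = {}
        p["W1a"] = nn.glorot(rng, (1, c1))
        p["W1b"] = nn.glorot(rng, (1, c1))
        p["b1"] = np.zeros(c1, dtype=nn.DTYPE)
        p["W2a"] = nn.glorot(rng, (c1, c2))
        p["W2b"] = nn.glorot(rng, (c1, c2))
        p["b2"] = np.zeros(c2, dtype=nn.DTYPE)
        p["attn"] = nn.glorot(rng, (c2, 1))[:, 0]
        widths = [c2, *cfg.dense_head, 1]
        for i in range(len(widths) - 1):
            p[f"Wd{i}"] = nn.glorot(rng, (widths[i], widths[i + 1]))
            p[f"bd{i}"] = np.zeros(widths[i + 1], dtype=nn.DTYPE)
        self.n_dense = len(widths) - 1
        self.params = p
        self.trained = False

    # -- forward -----------------------------------------------------------
    def _forward(self, Ahat: sp.csr_matrix, X: np.ndarray, gi: np.ndarray,
                 n_graphs: int, want_cache: bool = False):
        p = self.params
        a1, a2 = self.cfg.activations
        X = X.astype(nn.DTYPE)
        S0 = Ahat @ X
        P1 = S0 @ p["W1a"] + X @ p["W1b"] + p["b1"]
        Z1 = nn.activation(a1, P1)
        S1 = Ahat @ Z1
        P2 = S1 @ p["W2a"] + Z1 @ p["W2b"] + p["b2"]
        Z2 = nn.activation(a2, P2)
        scores = Z2 @ p["attn"]
        alpha = nn.segment_softmax(scores, gi, n_graphs)
        g = nn.segment_sum(alpha[:, None] * Z2, gi, n_graphs)
        hs = [g]
        pre = []
        H = g
        for i in range(self.n_dense):
            P = H @ p[f"Wd{i}"] + p[f"bd{i}"]
            pre.append(P)
            H = np.maximum(P, 0.0) if i < self.n_dense - 1 else 1.0 / (1.0 + np.exp(-P))
            hs.append(H)
        yhat = hs[-1][:, 0]
        if not want_cache:
            return yhat
        return yhat, (X, S0, P1, Z1, S1, P2, Z2, alpha, g, hs, pre)

    # -- backward ----------------------------------------------------------
    def _backward(self, Ahat, gi, n_graphs, cache, dyhat):
        p = self.params
        a1, a2 = self.cfg.activations
        X, S0, P1, Z1, S1, P2, Z2, alpha, g, hs, pre = cache
        grads: dict[str, np.ndarray] = {}
        out = hs[-1]
        delta = (dyhat[:, None] * out * (1.0 - out)).astype(nn.DTYPE)
        for i in range(self.n_dense - 1, -1, -1):
            grads[f"Wd{i}"] = hs[i].T @ delta
            grads[f"bd{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ p[f"Wd{i}"].T) * (pre[i - 1] > 0)
            else:
                dg = delta @ p[f"Wd{i}"].T
        # pooling backward
        r = (Z2 * dg[gi]).sum(axis=1)
        R = nn.segment_sum(alpha * r, gi, n_graphs)
        dscores = alpha * (r - R[gi])
        dZ2 = alpha[:, None] * dg[gi] + dscores[:, None] * p["attn"][None, :]
        grads["attn"] = Z2.T @ dscores
        dP2 = dZ2 * nn.activation_grad(a2, P2, Z2)
        grads["W2a"] = S1.T @ dP2
        grads["W2b"] = Z1.T @ dP2
        grads["b2"] = dP2.sum(axis=0)
        dZ1 = Ahat @ (dP2 @ p["W2a"].T) + dP2 @ p["W2b"].T
        dP1 = dZ1 * nn.activation_grad(a1, P1, Z1)
        grads["W1a"] = S0.T @ dP1
        grads["W1b"] = X.T @ dP1
        grads["b1"] = dP1.sum(axis=0)
        return grads

    # -- public API --------------------------------------------------------
    def predict(self, graphs: list[CellGraph] | GraphBatch) -> np.ndarray:
        """Predicted q per graph, in (0, 1)."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        batch = graphs if isinstance(graphs, GraphBatch) else disjoint_union(list(graphs))
        Ahat = nn.normalized_adjacency(
            batch.A if self.cfg.weighted_adjacency else (batch.A != 0).astype(nn.DTYPE))
        return self._forward(Ahat, batch.X, batch.graph_index, batch.n_graphs)


def _prep(graphs: list[CellGraph], weighted: bool):
    mats = []
    for g in graphs:
        A = g.adjacency(weighted=weighted)
        mats.append(nn.normalized_adjacency(A))
    X = [g.node_features.astype(nn.DTYPE) for g in graphs]
    y = np.array([g.label for g in graphs], dtype=nn.DTYPE)
    return mats, X, y


def _batch(mats, Xs, idx):
    A = sp.block_diag([mats[i] for i in idx], format="csr")
    X = np.vstack([Xs[i] for i in idx])
    gi = np.concatenate([np.full(Xs[i].shape[0], k, dtype=np.int64)
                         for k, i in enumerate(idx)])
    return A, X, gi, len(idx)


def train_recognizer(graphs: list[CellGraph], cfg: RecogTrainConfig
                     ) -> tuple[RecognizerModel, RecogEvalReport]:
    """Train the dispersion-parameter regressor on labeled cell graphs.

    Splits the graphs 80/10/10 into train/test/validation, optimizes the MSE
    with Adam, lowers the learning rate on validation plateaus and restores
    the best validation checkpoint before evaluating on the held-out test
    split.
    """
    if len(graphs) < 10:
        raise ValueError("need at least 10 labeled graphs to split 80/10/10")
    if any(g.label is None for g in graphs):
        raise ValueError("every graph must carry a q label for training")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(graphs))
    n = len(graphs)
    n_train = int(round(cfg.split[0] * n))
    n_test = int(round(cfg.split[1] * n))
    tr = order[:n_train]
    te = order[n_train:n_train + n_test]
    va = order[n_train + n_test:]
    if min(len(tr), len(te), len(va)) == 0:
        raise ValueError("a split is empty; provide more graphs")

    weighted = cfg.weighted_adjacency
    mats, Xs, y = _prep(graphs, weighted)
    model = RecognizerModel(cfg)
    opt = nn.Adam(model.params, lr=cfg.lr)

    va_batch = _batch(mats, Xs, va)
    te_batch = _batch(mats, Xs, te)

    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    plateau = 0
    since_best = 0
    history = []
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(tr))
        ep_loss = 0.0
        for start in range(0, len(tr), cfg.batch_size):
            idx = tr[perm[start:start + cfg.batch_size]]
            A, X, gi, ng = _batch(mats, Xs, idx)
            yhat, cache = model._forward(A, X, gi, ng, want_cache=True)
            err = yhat - y[idx]
            ep_loss += float(np.sum(err ** 2))
            dyhat = (2.0 / ng) * err
            opt.step(model._backward(A, gi, ng, cache, dyhat))
        val_pred = model._forward(*va_batch[:3], va_batch[3])
        val_mse = float(np.mean((val_pred - y[va]) ** 2))
        history.append({"epoch": epoch, "train_mse": ep_loss / len(tr),
                        "val_mse": val_mse, "lr": opt.lr})
        if val_mse < best_val - 1e-7:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in model.params.items()}
            plateau = 0
            since_best = 0
        else:
            plateau += 1
            since_best += 1
            if plateau >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                plateau = 0
            if since_best >= cfg.early_stop_patience:
                break
    model.params.update(best_params)
    model.trained = True

    test_pred = model._forward(*te_batch[:3], te_batch[3])
    err = np.abs(test_pred - y[te])
    report = RecogEvalReport(
        mse=float(np.mean(err ** 2)),
        max_error=float(err.max()),
        frac_below_005=float(np.mean(err < 0.05)),
        true_q=y[te].astype(float),
        pred_q=test_pred.astype(float),
        history=history,
    )
    return model, report


def predict_q(model: RecognizerModel, graphs: list[CellGraph]) -> np.ndarray:
    """Predict the dispersion parameter for each graph (node-permutation
    invariant and independent of how graphs are batched)."""
    return model.predict(graphs)


def hyperparameter_grid(graphs: list[CellGraph], grid: dict,
                        base: RecogTrainConfig | None = None) -> list[dict]:
    """Train every combination of the grid (channels x activation x learning
    rate, applied network-wide) with a fixed seed and rank configurations by
    validation MSE, then max test error."""
    base = base or RecogTrainConfig()
    channels = grid.get("channels", [base.channels])
    activations = grid.get("activation", [base.activations])
    lrs = grid.get("lr", [base.lr])
    results = []
    for c in channels:
        for a in activations:
            for lr in lrs:
                cfg = RecogTrainConfig(
                    channels=c if isinstance(c, tuple) else (c, c),
                    activations=a if isinstance(a, tuple) else (a, a),
                    dense_head=base.dense_head, lr=lr,
                    plateau_factor=base.plateau_factor,
                    plateau_patience=base.plateau_patience,
                    early_stop_patience=base.early_stop_patience,
                    max_epochs=base.max_epochs, batch_size=base.batch_size,
                    split=base.split, weighted_adjacency=base.weighted_adjacency,
                    seed=base.seed,
                )
                _, report = train_recognizer(graphs, cfg)
                val = min(h["val_mse"] for h in report.history)
                results.append({
                    "channels": cfg.channels, "activations": cfg.activations,
                    "lr": lr, "val_mse": val, "test_mse": report.mse,
                    "max_error": report.max_error,
                })
    return sorted(results, key=lambda r: (r["val_mse"], r["max_error"]))
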
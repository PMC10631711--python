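"""Fate imputation from nearest neighbours with a multilayer perceptron.

Each cell becomes one training row: the target is its own fate (2 classes
for simulated tissues, 4 for experimental-style organoids) and the features
are the fates F1..Fk and Euclidean distances D1..Dk of its k nearest
neighbours, ordered by ascending distance.  Neighbour coordinates are
deliberately not included.  The imputer is a perceptron with three hidden
layers of 64 ReLU units, a softmax output of width 2 or 4, Adam (learning
rate 1e-3) on sparse categorical cross-entropy, an autostop that halts
training after 75 epochs without validation-loss improvement and restores
the best checkpoint, and an 80/20 train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fatepattern.nn import SoftmaxMLP

__all__ = [
    "ImputerConfig",
    "ImputerEvalReport",
    "neighbor_features",
    "feature_matrix",
    "train_imputer",
    "neighbor_sweep",
    "crosstrain_matrix",
    "confusion",
    "majority_baseline",
]


@dataclass(frozen=True)
class ImputerConfig:
    hidden: tuple[int, ...] = (64, 64, 64)
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 400
    patience: int = 75
    test_fraction: float = 0.2
    val_fraction: float = 0.1  # carved out of the training split
    seed: int = 0


@dataclass
class ImputerEvalReport:
    accuracy: float
    confusion_counts: np.ndarray
    k: int
    n_classes: int
    y_true: np.ndarray = field(default_factory=lambda: np.array([]))
    y_pred: np.ndarray = field(default_factory=lambda: np.array([]))


def _cells_to_arrays(cells) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(cells, "pos"):  # Tissue
        if cells.fates is None:
            raise ValueError("tissue has no fates")
        return np.asarray(cells.pos, float), np.asarray(cells.fates, int)
    df = pd.DataFrame(cells)
    cols = ["CentroidX", "CentroidY"] + (["CentroidZ"] if "CentroidZ" in df.columns else [])
    fate_col = "class" if "class" in df.columns else "fate"
    return df[cols].to_numpy(float), df[fate_col].to_numpy(int)


def neighbor_features(cells, k: int) -> pd.DataFrame:
    """One row per cell: ``label, F1, D1, ..., Fk, Dk`` with neighbours in
    ascending distance order (ties broken by the smaller cell index).

    Exact k-nearest-neighbour queries on the Euclidean centroid distances;
    the cell itself is never among its own neighbours.
    """
    pos, fates = _cells_to_arrays(cells)
    n = len(pos)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cell count {n}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("coordinates must be finite")
    from scipy.spatial.distance import cdist

    d = cdist(pos, pos)
    np.fill_diagonal(d, np.inf)
    idx_base = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx_base, d), axis=1)[:, :k]  # distance, then index
    rows = np.arange(n)[:, None]
    nd = d[rows, order]
    nf = fates[order]
    data = {"label": fates}
    for j in range(k):
        data[f"F{j + 1}"] = nf[:, j]
        data[f"D{j + 1}"] = nd[:, j]
    return pd.DataFrame(data)


def feature_matrix(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Split a neighbour-feature table into (X, y, k)."""
    k = (rows.shape[1] - 1) // 2
    cols = [c for j in range(k) for c in (f"F{j + 1}", f"D{j + 1}")]
    return rows[cols].to_numpy(float), rows["label"].to_numpy(int), k


def _dataset_rows(cells_list, k: int) -> pd.DataFrame:
    if hasattr(cells_list, "pos") or isinstance(cells_list, pd.DataFrame):
        cells_list = [cells_list]
    return pd.concat([neighbor_features(c, k) for c in cells_list], ignore_index=True)


def train_imputer(rows: pd.DataFrame, n_classes: int = 2,
                  cfg: ImputerConfig | None = None
                  ) -> tuple[SoftmaxMLP, ImputerEvalReport]:
    """Train the fate-imputation perceptron on neighbour-feature rows."""
    cfg = cfg or ImputerConfig()
    if n_classes not in (2, 4):
        raise ValueError("n_classes must be 2 or 4")
    X, y, k = feature_matrix(rows)
    if len(np.unique(y)) < 2:
        raise ValueError("training rows contain a single class")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(y))
    n_test = int(round(cfg.test_fraction * len(y)))
    test, trainval = order[:n_test], order[n_test:]
    n_val = max(1, int(round(cfg.val_fraction * len(trainval))))
    val, train = trainval[:n_val], trainval[n_val:]

    model = SoftmaxMLP(X.shape[1], n_classes, hidden=cfg.hidden, lr=cfg.lr,
                       seed=cfg.seed)
    model.fit(X[train], y[train], X[val], y[val], batch_size=cfg.batch_size,
              max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed + 1)
    y_pred = model.predict(X[test])
    y_true = y[test]
    acc = float(np.mean(y_pred == y_true)) if len(y_true) else float("nan")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    report = ImputerEvalReport(accuracy=acc, confusion_counts=counts, k=k,
                               n_classes=n_classes, y_true=y_true, y_pred=y_pred)
    return model, report


def neighbor_sweep(cells_list, k_range, n_classes: int = 2,
                   cfg: ImputerConfig | None = None) -> dict:
    """Train one imputer per neighbour count k and report the accuracy curve
    and its arg-max (shared seed policy across k)."""
    cfg = cfg or ImputerConfig()
    accs = {}
    for k in k_range:
        rows = _dataset_rows(cells_list, k)
        _, report = train_imputer(rows, n_classes=n_classes, cfg=cfg)
        accs[int(k)] = report.accuracy
    best_k = max(accs, key=lambda kk: (accs[kk], -kk))
    return {"accuracy_by_k": accs, "best_k": best_k}


def crosstrain_matrix(datasets_by_q: dict, k: int,
                      cfg: ImputerConfig | None = None
                      ) -> tuple[list[float], np.ndarray]:
    """Accuracy matrix of imputers trained on one q level and tested on all.

    Entry (i, j) is the test accuracy of the model trained on the training
    split of q_i and evaluated on the held-out split of q_j.  Rows and
    columns follow the sorted q levels.
    """
    cfg = cfg or ImputerConfig()
    qs = sorted(datasets_by_q)
    if len(qs) < 2:
        raise ValueError("crosstraining needs at least two q levels")
    rng = np.random.default_rng(cfg.seed)
    split = {}
    for q in qs:
        X, y, _ = feature_matrix(_dataset_rows(datasets_by_q[q], k))
        order = rng.permutation(len(y))
        n_test = int(round(cfg.test_fraction * len(y)))
        split[q] = (X, y, order[n_test:], order[:n_test])
    M = np.zeros((len(qs), len(qs)))
    for i, qi in enumerate(qs):
        X, y, train, _ = split[qi]
        n_val = max(1, int(round(cfg.val_fraction * len(train))))
        val, tr = train[:n_val], train[n_val:]
        model = SoftmaxMLP(X.shape[1], 2, hidden=cfg.hidden, lr=cfg.lr, seed=cfg.seed)
        model.fit(X[tr], y[tr], X[val], y[val], batch_size=cfg.batch_size,
                  max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed + 1)
        for j, qj in enumerate(qs):
            Xj, yj, _, testj = split[qj]
            M[i, j] = float(np.mean(model.predict(Xj[testj]) == yj[testj]))
    return qs, M


def confusion(report: ImputerEvalReport) -> tuple[np.ndarray, np.ndarray]:
    """Count and row-normalized confusion matrices (rows = true labels)."""
    counts = report.confusion_counts
    if counts.sum() == 0:
        raise ValueError("empty test set; no confusion matrix")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, np.nan)
    return counts, norm


def majority_baseline(rows: pd.DataFrame, cfg: ImputerConfig | None = None) -> float:
    """Accuracy of always predicting the training split's majority class,
    using the same split policy as :func:`train_imputer`."""
    cfg = cfg or ImputerConfig()
    _, y, _ = feature_matrix(rows)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(y))
    n_test = int(round(cfg.test_fraction * len(y)))
    test, trainval = order[:n_test], order[n_test:]
    majority = np.bincount(y[trainval]).argmax()
    return float(np.mean(y[test] == majority))
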
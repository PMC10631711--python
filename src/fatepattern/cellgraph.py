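"""Delaunay cell graphs and disjoint-union batching.

Cells become graph nodes carrying their fate as the node feature.  Two cells
are joined by an edge when they are neighbours in the Delaunay triangulation
of the centroids *and* closer than a distance threshold: 2.0 for simulated
tissues (twice the maximum possible cell radius) or, for experimental-style
organoids, the mean Delaunay edge length plus two standard deviations.
Retained edge lengths are divided by the longest retained edge of the graph,
so edge weights lie in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from fatepattern._geometry import delaunay_edges

__all__ = ["CellGraph", "GraphBatch", "build_graph", "disjoint_union", "SIMULATED_THRESHOLD"]

SIMULATED_THRESHOLD = 2.0


@dataclass
class CellGraph:
    """Weighted undirected cell graph with per-node fates and an optional
    graph-level dispersion label q."""

    node_ids: np.ndarray  # (n,)
    node_features: np.ndarray  # (n, f) fate scalar(s)
    edges: np.ndarray  # (e, 2) with i < j
    edge_weights: np.ndarray  # (e,) normalized lengths in (0, 1]
    label: float | None = None
    kind: str = "simulated"
    threshold: float = SIMULATED_THRESHOLD
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if self.edges.size and (np.any(self.edge_weights <= 0) or np.any(self.edge_weights > 1)):
            raise ValueError("edge weights must lie in (0, 1]")
        if self.label is not None and not (0.0 < self.label < 1.0):
            raise ValueError("graph label q must lie in (0, 1)")
        if self.node_features.ndim == 1:
            self.node_features = self.node_features[:, None]

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def adjacency(self, weighted: bool = True) -> sp.csr_matrix:
        """Symmetric adjacency matrix A (weighted by normalized distance or
        binary)."""
        vals = self.edge_weights if weighted else np.ones(len(self.edge_weights))
        i, j = self.edges[:, 0], self.edges[:, 1]
        A = sp.coo_matrix(
            (np.concatenate([vals, vals]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        )
        return A.tocsr()

    def degrees(self, weighted: bool = False) -> np.ndarray:
        """Node degree vector (row sums of A)."""
        return np.asarray(self.adjacency(weighted=weighted).sum(axis=1)).ravel()


@dataclass
class GraphBatch:
    """Disjoint union of cell graphs: block-diagonal adjacency, stacked node
    features, per-node origin index and per-graph labels."""

    A: sp.csr_matrix
    X: np.ndarray
    graph_index: np.ndarray  # (n_total,) origin graph of each node
    labels: np.ndarray  # (n_graphs,) NaN where unlabeled
    n_graphs: int

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]


def _as_positions_and_fates(cells) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a Tissue or a cell-table DataFrame."""
    if hasattr(cells, "pos"):  # Tissue
        pos = np.asarray(cells.pos, dtype=float)
        fates = cells.fates
        if fates is None:
            raise ValueError("tissue has no fates; run the fate dynamics first")
        ids = np.arange(pos.shape[0])
        return pos, np.asarray(fates, dtype=float), ids
    df = pd.DataFrame(cells)
    cols = ["CentroidX", "CentroidY"] + (["CentroidZ"] if "CentroidZ" in df.columns else [])
    pos = df[cols].to_numpy(dtype=float)
    fate_col = "fate" if "fate" in df.columns else "class"
    if fate_col not in df.columns:
        raise ValueError("cell table needs a 'fate' (or 'class') column")
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    return pos, df[fate_col].to_numpy(dtype=float), ids


def build_graph(
    cells,
    kind: str = "simulated",
    label_q: float | None = None,
    threshold: float | None = None,
) -> CellGraph:
    """Build the thresholded Delaunay cell graph of a tissue or cell table.

    ``kind="simulated"`` uses the fixed threshold 2; ``kind="experimental"``
    derives it from that organoid's Delaunay edge lengths (mean + 2 SD).
    An explicit ``threshold`` overrides both.  Edge weights are edge lengths
    divided by the maximum retained edge length.
    """
    if kind not in ("simulated", "experimental"):
        raise ValueError(f"kind must be 'simulated' or 'experimental', got {kind!r}")
    pos, fates, ids = _as_positions_and_fates(cells)
    ii, jj, lengths = delaunay_edges(pos)
    if threshold is None:
        if kind == "simulated":
            threshold = SIMULATED_THRESHOLD
        else:
            threshold = float(lengths.mean() + 2.0 * lengths.std())
    keep = lengths < threshold
    ii, jj, lengths = ii[keep], jj[keep], lengths[keep]
    if len(lengths) == 0:
        edges = np.zeros((0, 2), dtype=int)
        weights = np.zeros(0)
    else:
        edges = np.column_stack([ii, jj])
        weights = lengths / lengths.max()
    if label_q is None:
        if isinstance(cells, pd.DataFrame) and "q" in cells.columns:
            vals = cells["q"].unique()
            label_q = float(vals[0]) if len(vals) == 1 else None
        elif hasattr(cells, "q"):
            label_q = cells.q
    if label_q is not None:
        label_q = float(label_q)
    return CellGraph(
        node_ids=np.asarray(ids), node_features=fates[:, None], edges=edges,
        edge_weights=weights, label=label_q, kind=kind, threshold=float(threshold),
        pos=pos,
    )


def disjoint_union(graphs: list[CellGraph]) -> GraphBatch:
    """Represent a batch of graphs as one block-diagonal graph.

    No edge crosses two member graphs; each node records the index of the
    graph it originated from so that pooling can act per graph.
    """
    if not graphs:
        raise ValueError("cannot batch an empty list of graphs")
    blocks = [g.adjacency(weighted=True) for g in graphs]
    A = sp.block_diag(blocks, format="csr")
    X = np.vstack([g.node_features for g in graphs])
    graph_index = np.concatenate([
        np.full(g.n, k, dtype=np.int64) for k, g in enumerate(graphs)
    ])
    labels = np.array([np.nan if g.label is None else g.label for g in graphs])
    return GraphBatch(A=A, X=X, graph_index=graph_index, labels=labels,
                      n_graphs=len(graphs))
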
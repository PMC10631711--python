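"""Shared Delaunay-edge extraction for tissues and cell graphs."""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError


def delaunay_edges(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unique Delaunay edges of a point set.

    Returns ``(i, j, length)`` arrays with i < j.  Raises ``ValueError``
    naming the geometry problem for degenerate inputs (collinear/coplanar
    points, too few points).
    """
    pos = np.asarray(pos, dtype=float)
    n, dim = pos.shape
    if n < dim + 1:
        raise ValueError(
            f"Delaunay triangulation needs at least {dim + 1} points in {dim}D, got {n}"
        )
    try:
        tri = Delaunay(pos)
    except QhullError as exc:  # pragma: no cover - message path
        raise ValueError(f"degenerate point set (Qhull: {str(exc).splitlines()[0]})") from exc
    simplices = tri.simplices
    k = simplices.shape[1]
    pairs = np.vstack([
        simplices[:, [a, b]] for a in range(k) for b in range(a + 1, k)
    ])
    pairs.sort(axis=1)
    pairs = np.unique(pairs, axis=0)
    lengths = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    return pairs[:, 0], pairs[:, 1], lengths
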
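"""Mapping between the four NANOG/GATA6 expression classes and binary fates.

The four classes are the standard ones of mouse preimplantation research:
epiblast precursors N+G- (high NANOG, low GATA6), primitive-endoderm
precursors N-G+ (low NANOG, high GATA6), uncommitted double-positive N+G+
and double-negative N-G- cells.  Numeric codes: N+G+ = 0, N-G+ = 1,
N-G- = 2, N+G- = 3.

Binary convention (shared with k-means clustering): GATA6-high cells are
labeled 0 and NANOG-high cells 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FATE_CODES", "FATE_NAMES", "assign_binary_random", "kmeans_binary"]

FATE_CODES = {"N+G+": 0, "N-G+": 1, "N-G-": 2, "N+G-": 3}
FATE_NAMES = {v: k for k, v in FATE_CODES.items()}

_COMMITTED_PRE = 1  # N-G+, maps to binary 0 (GATA6 high)
_COMMITTED_EPI = 3  # N+G-, maps to binary 1 (NANOG high)


def _as_codes(classes) -> np.ndarray:
    arr = np.asarray(classes)
    if arr.dtype.kind in "UOS":
        try:
            arr = np.array([FATE_CODES[str(c)] for c in arr])
        except KeyError as exc:
            raise ValueError(f"unknown fate class {exc.args[0]!r}") from exc
    arr = arr.astype(int)
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise ValueError("fate codes must lie in {0, 1, 2, 3}")
    return arr


def assign_binary_random(classes, seed: int = 0) -> np.ndarray:
    """Randomly assign the uncommitted classes to the two committed fates.

    Committed cells keep their fate: N-G+ -> 0, N+G- -> 1.  Each N+G+ or
    N-G- cell independently becomes 1 (N+G--like) with probability
    ``p = #N+G- / (#N+G- + #N-G+)``, so the expected type proportions are
    unchanged by the assignment.
    """
    codes = _as_codes(classes)
    n_epi = int(np.sum(codes == _COMMITTED_EPI))
    n_pre = int(np.sum(codes == _COMMITTED_PRE))
    if n_epi + n_pre == 0:
        raise ValueError("no committed (N+G- or N-G+) cells to anchor the assignment")
    p = n_epi / (n_epi + n_pre)
    out = np.empty(len(codes), dtype=np.int64)
    out[codes == _COMMITTED_EPI] = 1
    out[codes == _COMMITTED_PRE] = 0
    uncommitted = (codes == 0) | (codes == 2)
    rng = np.random.default_rng(seed)
    out[uncommitted] = (rng.random(int(uncommitted.sum())) < p).astype(np.int64)
    return out


def kmeans_binary(gata6, nanog, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Binarize cells by 2-means clustering of (log GATA6, log NANOG).

    The cluster with the higher mean GATA6 level is labeled 0, the other
    (NANOG-high) 1.  Expression values must be positive.
    """
    g = np.asarray(gata6, dtype=float)
    nn = np.asarray(nanog, dtype=float)
    if np.any(g <= 0) or np.any(nn <= 0):
        raise ValueError("expression values must be positive to take logarithms")
    X = np.column_stack([np.log(g), np.log(nn)])
    if np.allclose(X, X[0]):
        raise ValueError("all cells have identical expression; clustering is undefined")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    # cluster with high GATA6 -> 0
    mean_g = [X[raw == k, 0].mean() for k in (0, 1)]
    high_g = int(np.argmax(mean_g))
    return (raw != high_g).astype(np.int64)
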
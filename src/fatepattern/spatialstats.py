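"""Spatial summary statistics of two-type cell patterns.

Moran's index measures spatial autocorrelation of the binary fate vector on
the cell graph: values near -1 indicate alternating (checkerboard) patterns,
0 random mixing, and values approaching +1 full segregation of the two
types.  The pair correlation function (PCF) relates the observed number of
same-type cell pairs at a given distance to the chance of drawing two cells
of that type at random, so rho = 1 at all distances for randomly shuffled
fates, and a rise of one type's rho at the largest pair distances signals
enrichment of that type at the tissue rim.  Randomization envelopes
(default 1000 resamples) re-assign the uncommitted fate classes at random
and record the min/max of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fatepattern.cellgraph import CellGraph
from fatepattern import fates as fates_mod

__all__ = [
    "MoranResult",
    "PCFResult",
    "Envelope",
    "moran_index",
    "pcf",
    "random_fate_envelope",
    "match_q_by_pcf",
]


@dataclass(frozen=True)
class MoranResult:
    I: float
    n: int


@dataclass
class PCFResult:
    bin_centers: np.ndarray  # normalized distances in (0, 1]
    rho_u: np.ndarray  # type-0 correlation per bin (NaN where undefined)
    rho_v: np.ndarray  # type-1 correlation per bin
    counts: np.ndarray  # pairs per bin


@dataclass
class Envelope:
    lo: np.ndarray | float
    hi: np.ndarray | float
    R: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.lo) > np.asarray(self.hi)):
            raise ValueError("envelope min exceeds max")


def moran_index(graph: CellGraph, fates: np.ndarray) -> MoranResult:
    """Moran's index I = n/sum(A) * (x-xbar)' A (x-xbar) / (x-xbar)'(x-xbar).

    ``A`` is the binary adjacency of the cell graph.  The value does not
    depend on which fate is coded 0 and which 1.  Undefined (ValueError)
    for edgeless graphs or when all fates are equal.
    """
    x = np.asarray(fates, dtype=float)
    if x.shape[0] != graph.n:
        raise ValueError("fate vector length does not match graph size")
    A = graph.adjacency(weighted=False)
    total = A.sum()
    if total == 0:
        raise ValueError("Moran's index is undefined on an edgeless graph")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("Moran's index is undefined when all fates are equal")
    value = graph.n / total * float(xc @ (A @ xc)) / denom
    return MoranResult(I=float(value), n=graph.n)


def _positions(tissue) -> np.ndarray:
    import pandas as pd

    if isinstance(tissue, pd.DataFrame):
        cols = ["CentroidX", "CentroidY"] + (
            ["CentroidZ"] if "CentroidZ" in tissue.columns else [])
        return tissue[cols].to_numpy(dtype=float)
    if hasattr(tissue, "pos") and tissue.pos is not None:
        return np.asarray(tissue.pos, dtype=float)
    raise ValueError("need a Tissue or cell table with centroid positions")


def pcf(tissue, fates: np.ndarray, n_bins: int = 20) -> PCFResult:
    """Pair correlation functions of the two cell types.

    Pair distances are normalized by the maximum pair distance and collected
    in ``n_bins`` equal-width bins.  Within each bin,
    ``rho_t = (observed fraction of type-t/type-t pairs) / (n_t (n_t - 1) /
    (n (n - 1)))``, the hypergeometric expectation under random labeling
    with the observed type counts.  Empty bins give NaN; an absent type
    leaves its whole curve NaN.
    """
    pos = _positions(tissue)
    x = np.asarray(fates).astype(int)
    n = len(x)
    if pos.shape[0] != n:
        raise ValueError("fate vector length does not match cell count")
    from scipy.spatial.distance import pdist

    d = pdist(pos)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all cells coincide")
    bins = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.searchsorted(bins, d / dmax, side="left") - 1, 0, n_bins - 1)

    iu, ju = np.triu_indices(n, k=1)
    same0 = (x[iu] == 0) & (x[ju] == 0)
    same1 = (x[iu] == 1) & (x[ju] == 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    c0 = np.bincount(idx, weights=same0, minlength=n_bins)
    c1 = np.bincount(idx, weights=same1, minlength=n_bins)

    n0 = int(np.sum(x == 0))
    n1 = int(np.sum(x == 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho0 = (c0 / counts) / (n0 * (n0 - 1) / (n * (n - 1))) if n0 >= 2 else np.full(n_bins, np.nan)
        rho1 = (c1 / counts) / (n1 * (n1 - 1) / (n * (n - 1))) if n1 >= 2 else np.full(n_bins, np.nan)
    rho0 = np.where(counts > 0, rho0, np.nan)
    rho1 = np.where(counts > 0, rho1, np.nan)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return PCFResult(bin_centers=centers, rho_u=rho0, rho_v=rho1, counts=counts)


def random_fate_envelope(
    statistic: str,
    tissue,
    four_class_fates: np.ndarray,
    R: int = 1000,
    seed: int = 0,
    graph: CellGraph | None = None,
    n_bins: int = 20,
) -> Envelope:
    """Min/max envelope of Moran's I or the PCF over R random reassignments
    of the uncommitted fate classes (N+G+ and N-G-) to the two committed
    ones, preserving the committed cells and the expected type proportions.
    """
    if statistic not in ("moran", "pcf"):
        raise ValueError("statistic must be 'moran' or 'pcf'")
    classes = np.asarray(four_class_fates)
    if statistic == "moran" and graph is None:
        from fatepattern.cellgraph import build_graph

        kind = "experimental" if hasattr(tissue, "columns") else "simulated"
        graph = build_graph(tissue, kind=kind) if not isinstance(tissue, CellGraph) else tissue
    rng_seeds = np.random.SeedSequence(seed).generate_state(R)
    lo = hi = None
    for r in range(R):
        binary = fates_mod.assign_binary_random(classes, seed=int(rng_seeds[r]))
        if statistic == "moran":
            val = np.asarray(moran_index(graph, binary).I)
        else:
            res = pcf(tissue, binary, n_bins=n_bins)
            val = np.stack([res.rho_u, res.rho_v])
        if lo is None:
            lo = val.copy()
            hi = val.copy()
        else:
            lo = np.fmin(lo, val)
            hi = np.fmax(hi, val)
    if statistic == "moran":
        return Envelope(lo=float(lo), hi=float(hi), R=R)
    return Envelope(lo=lo, hi=hi, R=R)


def match_q_by_pcf(target: PCFResult, library: list[tuple[float, PCFResult]]) -> float:
    """Pick the library dispersion parameter whose PCF curves best match the
    target (pair-count-weighted mean squared deviation over both types;
    deterministic tie-break to the smaller q)."""
    if not library:
        raise ValueError("empty PCF library")
    best_q, best_score = None, np.inf
    for q, cand in sorted(library, key=lambda t: t[0]):
        if len(cand.bin_centers) != len(target.bin_centers) or not np.allclose(
            cand.bin_centers, target.bin_centers
        ):
            raise ValueError("library PCF binning does not match the target")
        score = 0.0
        weight = 0.0
        for a, b in ((target.rho_u, cand.rho_u), (target.rho_v, cand.rho_v)):
            ok = np.isfinite(a) & np.isfinite(b)
            w = target.counts[ok]
            score += float(np.sum(w * (a[ok] - b[ok]) ** 2))
            weight += float(np.sum(w))
        score = score / weight if weight > 0 else np.inf
        if score < best_score - 1e-12:
            best_score, best_q = score, q
    return best_q
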
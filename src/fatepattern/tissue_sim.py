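"""Agent-based simulation of 2D colonies and 3D organoids with binary fate patterns.

The simulation has two phases.  In the *growth* phase a single founder cell
divides repeatedly; daughters inherit a reduced radius ``r_new = 2**(-1/dim) *
r_old`` (so the total cell area/volume is conserved) and overlapping cells
relax by overdamped soft repulsion.  In the *fate* phase positions are frozen
and every cell carries two antagonistic transcription factors ``u`` and ``v``
coupled through a distance-dispersed intercellular signal.  A dispersion
parameter ``q`` in (0, 1) sets how far the signal reaches: cell j contributes
to cell i's signal with weight ``q**e_ij``, where ``e_ij`` is the centroid
distance in mean nearest-neighbour units (raised to a power > 1 beyond the
contact graph, so influence falls off superexponentially outside the contact
neighbourhood).  The signal is the row-normalized weighted mean of the
neighbours' ``u``, multiplied by a smooth centrality bias whose strength
grows with q.  Low ``q`` therefore couples only direct neighbours (lateral
inhibition, checkerboard patterns, negative spatial autocorrelation); high
``q`` integrates the whole tissue and the centrality bias pushes interior
cells to one fate and rim cells to the other (engulfing patterns).  See
``docs/methods.md`` for the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit

__all__ = [
    "GrowthParams",
    "FateParams",
    "Cell",
    "Tissue",
    "UnresolvedFateError",
    "GrowthError",
    "grow_tissue",
    "signal_weights",
    "run_fate_dynamics",
    "classify_fates",
    "balanced_filter",
    "simulate_dataset",
    "RECIPES",
]

# Mean cell-cycle times (simulation-time units), calibrated once so that a
# growth phase of T = 25 yields the mean tissue sizes of the discrete-q data
# sets: ~132 cells in 2D and ~330 cells in 3D.
CYCLE_TIME_2D = 3.56
CYCLE_TIME_3D = 3.00

_DEFAULT_ODE_PARAMS: Mapping[str, float] = {
    "hill": 4.0,  # Hill exponent of the mutual u<->v inhibition
    "theta": 0.5,  # inhibition threshold for u and v
    "signal_exponent": 3.0,  # exponent of the signal bias on v production
    "alpha_u": 1.0,  # maximal u production rate
    "alpha_v": 1.0,  # maximal v production rate
    "signal_cap": 3.0,  # upper clip of the normalized signal
    "far_exponent": 1.4,  # distance exponent of the beyond-contact decay
    "geometry_amp": 4.0,  # amplification of the centrality bias
    "geometry_scaling": 2.0,  # power of q scaling the centrality bias
    "geometry_range": 0.9,  # fixed mesoscale q of the centrality field
}


class GrowthError(RuntimeError):
    """Raised when the growth phase cannot satisfy its contract."""


class UnresolvedFateError(RuntimeError):
    """Raised when converged (u, v) levels do not separate into two fates."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the tissue-growth phase."""

    dim: int = 2
    t_growth: float = 30.0
    n_steps: int = 6000
    target_cells: int | None = None
    r_init: float = 1.0
    seed: int = 0
    cycle_time: float | None = None  # default: per-dimension calibrated value
    cycle_jitter: float = 0.25  # relative +- jitter of daughter cycle lengths
    repulsion: float = 50.0  # overdamped spring constant of overlap repulsion
    settle_steps: int = 200  # extra relaxation steps after the last division

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.target_cells is not None and self.target_cells < 1:
            raise ValueError("target_cells must be >= 1 when set")
        if self.r_init <= 0:
            raise ValueError("r_init must be > 0")
        if self.t_growth <= 0:
            raise ValueError("t_growth must be > 0")

    @property
    def dt(self) -> float:
        return self.t_growth / self.n_steps

    def resolved_cycle_time(self) -> float:
        if self.cycle_time is not None:
            return self.cycle_time
        return CYCLE_TIME_2D if self.dim == 2 else CYCLE_TIME_3D


@dataclass(frozen=True)
class FateParams:
    """Parameters of the fate-decision phase."""

    q: float
    t_fate: float = 100.0
    n_steps_fate: int = 1000
    init_band: float = 0.01
    seed: int = 0
    ode_params: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ODE_PARAMS))

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q must lie strictly in (0, 1), got {self.q}")
        if self.n_steps_fate < 1:
            raise ValueError("n_steps_fate must be >= 1")
        if self.init_band < 0:
            raise ValueError("init_band must be >= 0")

    @property
    def dt(self) -> float:
        return self.t_fate / self.n_steps_fate


@dataclass(frozen=True)
class Cell:
    cell_id: int
    pos: np.ndarray
    radius: float
    u: float | None = None
    v: float | None = None
    fate: int | None = None


@dataclass
class Tissue:
    """A simulated 2D colony or 3D organoid stored as flat arrays."""

    pos: np.ndarray  # (n, dim) centroids
    radii: np.ndarray  # (n,)
    dim: int
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    fates: np.ndarray | None = None  # (n,) int, values in {0, 1}
    q: float | None = None
    tissue_id: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != self.dim:
            raise ValueError("pos must have shape (n, dim)")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("positions must be finite")
        if np.any(np.asarray(self.radii) <= 0):
            raise ValueError("radii must be > 0")

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    @property
    def cells(self) -> list[Cell]:
        u = self.u if self.u is not None else [None] * self.n_cells
        v = self.v if self.v is not None else [None] * self.n_cells
        f = self.fates if self.fates is not None else [None] * self.n_cells
        return [
            Cell(i, self.pos[i], float(self.radii[i]),
                 None if u[i] is None else float(u[i]),
                 None if v[i] is None else float(v[i]),
                 None if f[i] is None else int(f[i]))
            for i in range(self.n_cells)
        ]

    def mean_nn_distance(self) -> float:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.pos).query(self.pos, k=2)
        return float(np.mean(d[:, 1]))


# ---------------------------------------------------------------------------
# growth phase
# ---------------------------------------------------------------------------

@njit(cache=True)
def _unit_direction(dim: int) -> np.ndarray:
    vec = np.empty(3)
    while True:
        norm2 = 0.0
        for k in range(dim):
            vec[k] = np.random.normal()
            norm2 += vec[k] * vec[k]
        if norm2 > 1e-12:
            break
    norm = np.sqrt(norm2)
    for k in range(dim):
        vec[k] /= norm
    for k in range(dim, 3):
        vec[k] = 0.0
    return vec


@njit(cache=True)
def _grow_kernel(dim, dt, n_steps, target, r_init, tau, jitter, k_rep,
                 settle_steps, seed, cap):
    """Growth loop: divisions on a jittered cell-cycle clock plus overdamped
    pairwise repulsion of overlapping cells.  Returns (pos, radii, n, ok)."""
    np.random.seed(seed)
    pos = np.zeros((cap, 3))
    rad = np.zeros(cap)
    tdiv = np.zeros(cap)
    rad[0] = r_init
    tdiv[0] = tau * (1.0 - jitter + 2.0 * jitter * np.random.random()) * np.random.random()
    n = 1
    shrink = 2.0 ** (-1.0 / dim)

    max_pairs = cap * 48
    pi = np.empty(max_pairs, dtype=np.int64)
    pj = np.empty(max_pairs, dtype=np.int64)
    n_pairs = 0
    stale = True

    reached = target > 0 and n >= target
    total_steps = n_steps + settle_steps
    step = 0
    while step < total_steps:
        t = (step + 1) * dt
        growing = step < n_steps and not reached
        if growing:
            n_now = n
            for i in range(n_now):
                if tdiv[i] <= t and n < cap:
                    d = _unit_direction(dim)
                    r_new = rad[i] * shrink
                    half = 0.5 * r_new
                    for k in range(3):
                        pos[n, k] = pos[i, k] - half * d[k]
                        pos[i, k] = pos[i, k] + half * d[k]
                    rad[i] = r_new
                    rad[n] = r_new
                    tdiv[i] = t + tau * (1.0 - jitter + 2.0 * jitter * np.random.random())
                    tdiv[n] = t + tau * (1.0 - jitter + 2.0 * jitter * np.random.random())
                    n += 1
                    stale = True
                    if target > 0 and n >= target:
                        reached = True
                        break
            if reached:
                # growth halts at this step; remaining budget only settles
                if settle_steps > 0:
                    total_steps = step + settle_steps
        if stale or step % 15 == 0:
            n_pairs = 0
            for i in range(n):
                for j in range(i + 1, n):
                    cut = 1.8 * (rad[i] + rad[j])
                    d2 = 0.0
                    for k in range(dim):
                        dd = pos[i, k] - pos[j, k]
                        d2 += dd * dd
                    if d2 < cut * cut and n_pairs < max_pairs:
                        pi[n_pairs] = i
                        pj[n_pairs] = j
                        n_pairs += 1
            stale = False
        # overdamped repulsion of overlapping pairs
        for p in range(n_pairs):
            i = pi[p]
            j = pj[p]
            d2 = 0.0
            for k in range(dim):
                dd = pos[i, k] - pos[j, k]
                d2 += dd * dd
            d = np.sqrt(d2)
            contact = rad[i] + rad[j]
            if d < 1e-9:
                # coincident centroids: push apart along a random direction
                dvec = _unit_direction(dim)
                eps = 0.01 * contact
                for k in range(3):
                    pos[i, k] += eps * dvec[k]
                    pos[j, k] -= eps * dvec[k]
                continue
            if d < contact:
                f = k_rep * (contact - d) / d
                for k in range(dim):
                    dd = pos[i, k] - pos[j, k]
                    pos[i, k] += dt * f * dd
                    pos[j, k] -= dt * f * dd
        step += 1
    ok = (target <= 0) or reached
    return pos[:n, :dim].copy(), rad[:n].copy(), n, ok


def grow_tissue(params: GrowthParams) -> Tissue:
    """Grow a tissue from a single founder cell.

    Stops as soon as ``target_cells`` is reached (when set) or after
    ``n_steps`` otherwise.  Raises :class:`GrowthError` naming the count
    reached if the target is unreachable within the step budget.
    """
    target = params.target_cells or 0
    if target > 0:
        cap = target
    else:
        tau = params.resolved_cycle_time()
        cap = int(8 * 2 ** (params.t_growth / (tau * (1 - params.cycle_jitter)))) + 16
        cap = min(cap, 1 << 14)
    pos, rad, n, ok = _grow_kernel(
        params.dim, params.dt, params.n_steps, target, params.r_init,
        params.resolved_cycle_time(), params.cycle_jitter, params.repulsion,
        params.settle_steps, params.seed % (2 ** 31), cap,
    )
    if not ok:
        raise GrowthError(
            f"target of {target} cells unreachable within {params.n_steps} steps; "
            f"reached {n} cells"
        )
    return Tissue(pos=pos, radii=rad, dim=params.dim,
                  provenance={"growth": params.__dict__.copy()})


# ---------------------------------------------------------------------------
# fate phase
# ---------------------------------------------------------------------------

def _normalized_distances(pos: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(pos))
    n = d.shape[0]
    scale = np.mean(np.min(d + np.diag(np.full(n, np.inf)), axis=1))
    return d / scale


def _dispersion_kernel(tissue: Tissue, q: float, far_exponent: float = 1.4,
                       dhat: np.ndarray | None = None) -> np.ndarray:
    """Raw dispersion kernel K_ij = q**e_ij with zero diagonal.

    The kernel exponent is the Euclidean centroid distance in units of the
    mean nearest-neighbour distance, floored at one unit; beyond the
    Delaunay contact graph (thresholded at 2, twice the maximum possible
    cell radius) the exponent is raised to ``far_exponent`` > 1, so the
    signal decays superexponentially outside the contact neighbourhood.
    """
    if tissue.n_cells < 2:
        raise ValueError("signal dispersion requires at least two cells")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    from fatepattern._geometry import delaunay_edges

    if dhat is None:
        dhat = np.maximum(_normalized_distances(tissue.pos), 1.0)
    e = np.power(dhat, far_exponent)
    ii, jj, lengths = delaunay_edges(tissue.pos)
    keep = lengths < 2.0
    e[ii[keep], jj[keep]] = dhat[ii[keep], jj[keep]]
    e[jj[keep], ii[keep]] = dhat[jj[keep], ii[keep]]
    K = np.power(q, e)
    np.fill_diagonal(K, 0.0)
    return K


def signal_weights(tissue: Tissue, q: float) -> np.ndarray:
    """Row-stochastic signal weight matrix w_ij = q**d_ij / sum_k q**d_ik.

    ``d_ij`` is the Euclidean centroid distance in units of the mean
    nearest-neighbour distance.  Rows sum to one; weights are non-increasing
    in distance for fixed q; the q->0 limit concentrates each row on the
    nearest cell(s) and the q->1 limit is uniform over all other cells.
    """
    if tissue.n_cells < 2:
        raise ValueError("signal dispersion requires at least two cells")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    K = np.power(q, _normalized_distances(tissue.pos))
    np.fill_diagonal(K, 0.0)
    return K / K.sum(axis=1, keepdims=True)


def classify_fates(u, v, tol: float = 1e-3):
    """Threshold converged (u, v) into fate 0 (u+v-) or 1 (u-v+).

    Scalar inputs return an int; array inputs return an int array.  Raises
    :class:`UnresolvedFateError` if any cell has |u - v| <= tol.
    """
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if np.any(u_arr < 0) or np.any(v_arr < 0):
        raise ValueError("u and v must be non-negative")
    diff = u_arr - v_arr
    unresolved = np.abs(diff) <= tol
    if np.any(unresolved):
        raise UnresolvedFateError(
            f"{int(np.sum(unresolved))} cell(s) with |u - v| <= {tol}"
        )
    fates = (diff < 0).astype(np.int64)
    if fates.ndim == 0:
        return int(fates)
    return fates


def _centrality_bias(dhat: np.ndarray, q: float, p: Mapping[str, float]) -> np.ndarray:
    """Per-cell multiplicative signal bias from tissue geometry.

    A fixed mesoscale kernel (dispersion ``geometry_range``) integrates the
    whole tissue, giving a smooth centrality field that is high in the
    interior and low at the rim.  Its influence scales as
    ``geometry_amp * q**geometry_scaling``: negligible for short-range
    signalling, dominant as q -> 1, where it drives the engulfing pattern.
    """
    G = np.power(p["geometry_range"], dhat)
    np.fill_diagonal(G, 0.0)
    mass = G.sum(axis=1)
    return np.power(mass / mass.mean(), p["geometry_amp"] * q ** p["geometry_scaling"])


@njit(cache=True)
def _fate_euler(K, g, mass, u, v, n_steps, dt, hill, theta_k, m, cap,
                alpha_u, alpha_v):
    """Forward-Euler integration of the mutual-inhibition dynamics with the
    row-normalized, centrality-biased dispersed signal (float32)."""
    n = u.shape[0]
    for step in range(n_steps):
        s = np.dot(K, u)
        um = u.mean()
        for i in range(n):
            si = g[i] * s[i] / (mass[i] * um)
            if si > cap:
                si = cap
            elif si < 0.0:
                si = 0.0
            inh_v = theta_k / (theta_k + v[i] ** hill)
            inh_u = theta_k / (theta_k + u[i] ** hill)
            un = u[i] + dt * (alpha_u * inh_v - u[i])
            vn = v[i] + dt * (alpha_v * si ** m * inh_u - v[i])
            u[i] = un if un > 0.0 else 0.0
            v[i] = vn if vn > 0.0 else 0.0
        if step % 100 == 99:
            for i in range(n):
                if not (np.isfinite(u[i]) and np.isfinite(v[i])):
                    return step
    return -1


def _integrate_fate(K: np.ndarray, g: np.ndarray, fp: FateParams,
                    rng: np.random.Generator):
    p = {**_DEFAULT_ODE_PARAMS, **dict(fp.ode_params)}
    n = K.shape[0]
    u = (0.5 + fp.init_band * rng.uniform(-1.0, 1.0, size=n)).astype(np.float32)
    v = (0.5 + fp.init_band * rng.uniform(-1.0, 1.0, size=n)).astype(np.float32)
    K = np.ascontiguousarray(K, dtype=np.float32)
    mass = K.sum(axis=1)
    bad_step = _fate_euler(
        K, g.astype(np.float32), mass, u, v, fp.n_steps_fate,
        np.float32(fp.dt), np.float32(p["hill"]),
        np.float32(p["theta"] ** p["hill"]), np.float32(p["signal_exponent"]),
        np.float32(p["signal_cap"]), np.float32(p["alpha_u"]),
        np.float32(p["alpha_v"]))
    if bad_step >= 0:
        raise FloatingPointError(f"non-finite state by fate step {bad_step}")
    return u.astype(float), v.astype(float)


def run_fate_dynamics(tissue: Tissue, fp: FateParams) -> Tissue:
    """Run the fate-decision dynamics on frozen positions.

    Returns a new :class:`Tissue` carrying converged (u, v) per cell and a
    binary fate from :func:`classify_fates`.  If any cell is left unresolved
    the integration is rerun once with a fresh initial-noise seed, then fails.
    """
    p = {**_DEFAULT_ODE_PARAMS, **dict(fp.ode_params)}
    dhat = np.maximum(_normalized_distances(tissue.pos), 1.0)
    K = _dispersion_kernel(tissue, fp.q, far_exponent=p["far_exponent"], dhat=dhat)
    g = _centrality_bias(dhat, fp.q, p)
    for attempt in range(2):
        rng = np.random.default_rng(np.random.SeedSequence([fp.seed, attempt]))
        u, v = _integrate_fate(K, g, fp, rng)
        try:
            fates = classify_fates(u, v)
        except UnresolvedFateError:
            if attempt == 1:
                raise
            continue
        return Tissue(
            pos=tissue.pos.copy(), radii=tissue.radii.copy(), dim=tissue.dim,
            u=u, v=v, fates=fates, q=fp.q, tissue_id=tissue.tissue_id,
            provenance={**tissue.provenance, "fate": {**fp.__dict__, "attempt": attempt}},
        )
    raise AssertionError("unreachable")


def balanced_filter(tissue: Tissue) -> bool:
    """True iff neither fate exceeds two thirds of the cells (strictly)."""
    if tissue.fates is None:
        raise ValueError("tissue has no fates assigned")
    n = tissue.n_cells
    counts = np.bincount(tissue.fates, minlength=2)
    return bool(3 * counts.max() <= 2 * n)


# ---------------------------------------------------------------------------
# data-set recipes
# ---------------------------------------------------------------------------

RECIPES = ("A", "B", "C", "D")
_Q_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))


def _simulate_one(dim, growth_kw, q, seed_pair, tissue_id):
    g_seed, f_seed = seed_pair
    tissue = grow_tissue(GrowthParams(dim=dim, seed=g_seed, **growth_kw))
    tissue.tissue_id = tissue_id
    return run_fate_dynamics(tissue, FateParams(q=q, seed=f_seed))


def simulate_dataset(
    recipe: str,
    seed: int,
    n_replicates: int | None = None,
    growth_time_range: tuple[float, float] | None = None,
) -> list[Tissue]:
    """Simulate one of the four study data sets.

    - ``A``: 2D colonies of exactly 150 cells (growth T=30, 6000 steps),
      q ~ U(0,1), tissues with more than 2/3 of one fate excluded;
      ``n_replicates`` is the number attempted (default 4000).
    - ``B``: 3D organoids, growth time ~ U over ``growth_time_range``
      (default (23.09, 27.06)), q ~ U(0,1), same balance filter
      (default 1000 attempts).
    - ``C``/``D``: 2D/3D, growth T=25 with 6000 steps, ``n_replicates``
      (default 100) tissues per q on the grid 0.1, 0.2, ..., 0.9, unfiltered.
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; expected one of {RECIPES}")
    root = np.random.SeedSequence([seed, RECIPES.index(recipe)])
    tissues: list[Tissue] = []

    if recipe in ("A", "B"):
        n_rep = n_replicates if n_replicates is not None else (4000 if recipe == "A" else 1000)
        rng = np.random.default_rng(root.spawn(1)[0])
        tid = 0
        for k in range(n_rep):
            q = float(rng.uniform(0.0, 1.0))
            if not (1e-6 < q < 1.0 - 1e-6):
                continue
            g_seed = int(rng.integers(0, 2 ** 31 - 1))
            f_seed = int(rng.integers(0, 2 ** 31 - 1))
            if recipe == "A":
                growth_kw = dict(t_growth=30.0, n_steps=6000, target_cells=150)
            else:
                lo, hi = growth_time_range or (23.09, 27.06)
                growth_kw = dict(t_growth=float(rng.uniform(lo, hi)), n_steps=6000)
            tissue = _simulate_one(2 if recipe == "A" else 3, growth_kw, q,
                                   (g_seed, f_seed), tid)
            if balanced_filter(tissue):
                tissues.append(tissue)
                tid += 1
        return tissues

    n_rep = n_replicates if n_replicates is not None else 100
    rng = np.random.default_rng(root.spawn(1)[0])
    dim = 2 if recipe == "C" else 3
    tid = 0
    for q in _Q_GRID:
        for _ in range(n_rep):
            g_seed = int(rng.integers(0, 2 ** 31 - 1))
            f_seed = int(rng.integers(0, 2 ** 31 - 1))
            tissues.append(_simulate_one(
                dim, dict(t_growth=25.0, n_steps=6000), q, (g_seed, f_seed), tid))
            tid += 1
    return tissues
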
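import numpy as np
import pytest

from fatepattern.cellgraph import CellGraph, build_graph
from fatepattern.spatialstats import (
    Envelope,
    match_q_by_pcf,
    moran_index,
    pcf,
    random_fate_envelope,
)
from fatepattern.tissue_sim import Tissue
from tests.conftest import random_tissue


def graph_from_edges(n, edges, fates=None):
    edges = np.asarray(edges)
    return CellGraph(node_ids=np.arange(n),
                     node_features=np.zeros((n, 1)) if fates is None else np.asarray(fates, float)[:, None],
                     edges=edges, edge_weights=np.ones(len(edges)) * 0.5)


def brute_force_moran(A, x):
    """Literal double-loop evaluation of the Moran's index formula."""
    n = len(x)
    xbar = x.mean()
    num = 0.0
    den = 0.0
    ssum = 0.0
    for i in range(n):
        den += (x[i] - xbar) ** 2
        for j in range(n):
            num += A[i, j] * (x[i] - xbar) * (x[j] - xbar)
            ssum += A[i, j]
    return n / ssum * num / den


class TestMoran:
    def test_alternating_four_cycle_is_minus_one(self):
        g = graph_from_edges(4, [[0, 1], [1, 2], [2, 3], [0, 3]])
        x = np.array([1, 0, 1, 0])
        assert moran_index(g, x).I == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 50))
            t = random_tissue(rng, n)
            g = build_graph(t, threshold=3.0)
            if len(g.edges) == 0:
                continue
            I = moran_index(g, t.fates).I
            oracle = brute_force_moran(g.adjacency(weighted=False).toarray(),
                                       t.fates.astype(float))
            assert I == pytest.approx(oracle, abs=1e-10)

    def test_label_swap_invariance(self, checkerboard150):
        g = build_graph(checkerboard150)
        a = moran_index(g, checkerboard150.fates).I
        b = moran_index(g, 1 - checkerboard150.fates).I
        assert a == pytest.approx(b, abs=1e-12)

    def test_two_cliques_with_bridge_positive(self):
        edges = [[0, 1], [0, 2], [1, 2], [3, 4], [3, 5], [4, 5], [2, 3]]
        g = graph_from_edges(6, edges)
        x = np.array([0, 0, 0, 1, 1, 1])
        I = moran_index(g, x).I
        assert I > 0
        assert I == pytest.approx(
            brute_force_moran(g.adjacency(weighted=False).toarray(), x.astype(float)),
            abs=1e-12)

    def test_permutation_invariance_of_cell_order(self):
        rng = np.random.default_rng(4)
        t = random_tissue(rng, 30)
        g = build_graph(t, threshold=3.0)
        perm = rng.permutation(30)
        inv = np.argsort(perm)
        pos2 = t.pos[perm]
        t2 = Tissue(pos=pos2, radii=t.radii, dim=2, fates=t.fates[perm])
        g2 = build_graph(t2, threshold=3.0)
        assert moran_index(g, t.fates).I == pytest.approx(
            moran_index(g2, t2.fates).I, abs=1e-10)

    def test_undefined_cases(self):
        g = graph_from_edges(4, [[0, 1]])
        with pytest.raises(ValueError):
            moran_index(g, np.array([1, 1, 1, 1]))
        empty = CellGraph(node_ids=np.arange(3), node_features=np.zeros((3, 1)),
                          edges=np.zeros((0, 2), dtype=int), edge_weights=np.zeros(0))
        with pytest.raises(ValueError):
            moran_index(empty, np.array([0, 1, 0]))


class TestPCF:
    def test_exhaustive_pair_oracle_small_instance(self):
        pos = np.array([[0, 0], [1, 0], [0, 1], [3, 3]], dtype=float)
        fates = np.array([0, 0, 1, 1])
        t = Tissue(pos=pos, radii=np.ones(4), dim=2, fates=fates)
        res = pcf(t, fates, n_bins=4)
        # brute force: all 6 pairs, dmax = sqrt(18)
        from itertools import combinations
        dmax = np.sqrt(18)
        pairs = list(combinations(range(4), 2))
        for b in range(4):
            lo, hi = b / 4, (b + 1) / 4
            in_bin = [(i, j) for i, j in pairs
                      if lo < np.linalg.norm(pos[i] - pos[j]) / dmax <= hi
                      or (b == 0 and np.linalg.norm(pos[i] - pos[j]) / dmax <= hi)]
            if not in_bin:
                assert np.isnan(res.rho_u[b]) and np.isnan(res.rho_v[b])
                continue
            same0 = sum(fates[i] == 0 and fates[j] == 0 for i, j in in_bin)
            same1 = sum(fates[i] == 1 and fates[j] == 1 for i, j in in_bin)
            exp_frac = (2 * 1) / (4 * 3)
            assert res.rho_u[b] == pytest.approx(same0 / len(in_bin) / exp_frac)
            assert res.rho_v[b] == pytest.approx(same1 / len(in_bin) / exp_frac)

    def test_random_labels_give_unit_pcf(self):
        rng = np.random.default_rng(8)
        pos = rng.random((1000, 2)) * 20
        fates = rng.permutation(np.r_[np.zeros(500, int), np.ones(500, int)])
        t = Tissue(pos=pos, radii=np.ones(1000), dim=2, fates=fates)
        res = pcf(t, fates)
        ok = res.counts > 50  # bins with enough pairs for the stochastic bound
        assert np.nanmax(np.abs(res.rho_u[ok] - 1)) < 0.2
        assert np.nanmax(np.abs(res.rho_v[ok] - 1)) < 0.2

    def test_label_swap_swaps_curves(self, checkerboard150):
        a = pcf(checkerboard150, checkerboard150.fates)
        b = pcf(checkerboard150, 1 - checkerboard150.fates)
        assert np.allclose(a.rho_u, b.rho_v, equal_nan=True)
        assert np.allclose(a.rho_v, b.rho_u, equal_nan=True)

    def test_engulfing_toy_rim_type_rises_at_max_distance(self):
        rng = np.random.default_rng(1)
        inner = rng.normal(scale=0.5, size=(60, 2))
        angle = rng.random(60) * 2 * np.pi
        outer = np.c_[3 * np.cos(angle), 3 * np.sin(angle)] + rng.normal(scale=0.1, size=(60, 2))
        pos = np.vstack([inner, outer])
        fates = np.r_[np.ones(60, int), np.zeros(60, int)]
        t = Tissue(pos=pos, radii=np.ones(120), dim=2, fates=fates)
        res = pcf(t, fates)
        last = max(i for i in range(20) if np.isfinite(res.rho_u[i]))
        assert res.rho_u[last] > 1.5  # type 0 = rim

    def test_absent_type_flagged_nan(self):
        pos = np.random.default_rng(0).random((10, 2))
        t = Tissue(pos=pos, radii=np.ones(10), dim=2)
        res = pcf(t, np.zeros(10, int))
        assert np.all(np.isnan(res.rho_v))


class TestEnvelope:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        t = random_tissue(rng, 60)
        classes = rng.integers(0, 4, 60)
        classes[:6] = 1  # committed cells present
        classes[6:12] = 3
        return t, classes

    def test_r_equals_one_degenerate(self):
        t, classes = self._setup()
        env = random_fate_envelope("moran", t, classes, R=1, seed=5,
                                   graph=build_graph(t, threshold=3.0))
        assert env.lo == env.hi

    def test_no_uncommitted_cells_deterministic(self):
        t, _ = self._setup()
        classes = np.r_[np.ones(30, int), np.full(30, 3)]
        env = random_fate_envelope("moran", t, classes, R=25, seed=5,
                                   graph=build_graph(t, threshold=3.0))
        assert env.lo == env.hi

    def test_envelope_contains_extra_samples(self):
        from fatepattern.fates import assign_binary_random
        t, classes = self._setup(3)
        g = build_graph(t, threshold=3.0)
        env = random_fate_envelope("moran", t, classes, R=300, seed=5, graph=g)
        for s in range(15):
            binary = assign_binary_random(classes, seed=10_000 + s)
            val = moran_index(g, binary).I
            assert env.lo - 1e-12 <= val <= env.hi + 1e-12

    def test_increasing_r_never_narrows(self):
        t, classes = self._setup(4)
        g = build_graph(t, threshold=3.0)
        small = random_fate_envelope("moran", t, classes, R=40, seed=9, graph=g)
        large = random_fate_envelope("moran", t, classes, R=120, seed=9, graph=g)
        assert large.lo <= small.lo and large.hi >= small.hi

    def test_pcf_envelope_shape(self):
        t, classes = self._setup(6)
        env = random_fate_envelope("pcf", t, classes, R=10, seed=1)
        assert np.all(np.asarray(env.lo) <= np.asarray(env.hi) + 1e-12) or np.isnan(env.lo).any()

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            Envelope(lo=np.array([1.0]), hi=np.array([0.0]), R=2)


class TestMatchQ:
    def _pcf_at(self, tissue, fates):
        return pcf(tissue, fates)

    def test_exact_member_recovered(self, checkerboard150, engulfing150):
        lib = [(0.05, pcf(checkerboard150, checkerboard150.fates)),
               (0.95, pcf(engulfing150, engulfing150.fates))]
        assert match_q_by_pcf(lib[1][1], lib) == 0.95

    def test_tie_breaks_to_smaller_q(self):
        base = pcf(Tissue(pos=np.random.default_rng(0).random((50, 2)), radii=np.ones(50),
                          dim=2), np.r_[np.zeros(25, int), np.ones(25, int)])
        import copy
        a = copy.deepcopy(base)
        b = copy.deepcopy(base)
        a.rho_u = base.rho_u + 0.1
        b.rho_u = base.rho_u - 0.1
        assert match_q_by_pcf(base, [(0.4, b), (0.2, a)]) == 0.2

    def test_single_member_library(self, checkerboard150, engulfing150):
        lib = [(0.7, pcf(engulfing150, engulfing150.fates))]
        target = pcf(checkerboard150, checkerboard150.fates)
        assert match_q_by_pcf(target, lib) == 0.7

    def test_binning_mismatch_rejected(self, checkerboard150):
        a = pcf(checkerboard150, checkerboard150.fates, n_bins=20)
        b = pcf(checkerboard150, checkerboard150.fates, n_bins=10)
        with pytest.raises(ValueError):
            match_q_by_pcf(a, [(0.5, b)])
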
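import numpy as np
import pytest

from fatepattern import tissue_sim as ts
from fatepattern.tissue_sim import (
    FateParams,
    GrowthError,
    GrowthParams,
    Tissue,
    UnresolvedFateError,
    balanced_filter,
    classify_fates,
    grow_tissue,
    run_fate_dynamics,
    signal_weights,
    simulate_dataset,
)


def _tissue_from(pos, fates=None, dim=None):
    pos = np.asarray(pos, float)
    dim = dim or pos.shape[1]
    return Tissue(pos=pos, radii=np.ones(len(pos)), dim=dim,
                  fates=None if fates is None else np.asarray(fates))


class TestGrowth:
    @pytest.mark.parametrize("dim,expected", [(2, 2 ** -0.5), (3, 2 ** (-1 / 3))])
    def test_radius_rule_exact(self, dim, expected):
        """Daughter radii are r_old * 2**(-1/dim) to machine precision, so
        every radius is an exact power of the shrink factor."""
        t = grow_tissue(GrowthParams(dim=dim, t_growth=12, n_steps=1200, seed=1))
        assert t.n_cells > 4
        gens = np.log(t.radii) / np.log(expected)
        assert np.allclose(gens, np.round(gens), atol=1e-12)

    def test_target_cell_count_is_exact(self, colony150):
        assert colony150.n_cells == 150

    def test_unreachable_target_raises_with_count(self):
        with pytest.raises(GrowthError, match=r"reached \d+ cells"):
            grow_tissue(GrowthParams(dim=2, t_growth=0.1, n_steps=20,
                                     target_cells=1000, seed=0))

    def test_no_coincident_centroids(self, colony150):
        from scipy.spatial.distance import pdist
        assert pdist(colony150.pos).min() > 0

    def test_identical_seeds_bit_identical(self):
        p = GrowthParams(dim=2, t_growth=10, n_steps=1000, seed=77)
        a, b = grow_tissue(p), grow_tissue(p)
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.radii, b.radii)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(dim=4)
        with pytest.raises(ValueError):
            GrowthParams(r_init=0.0)
        with pytest.raises(ValueError):
            FateParams(q=1.0)


class TestSignalWeights:
    def test_two_cells_forced_by_normalization(self):
        t = _tissue_from([[0.0, 0.0], [1.0, 0.0]])
        W = signal_weights(t, 0.37)
        assert np.allclose(W, [[0, 1], [1, 0]])

    def test_three_collinear_cells_hand_computed(self):
        # distances 1 and 2 from cell 0 with q=0.5: w01 = 0.5/0.75, w02 = 0.25/0.75
        t = _tissue_from([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = signal_weights(t, 0.5)
        assert W[0, 1] == pytest.approx(2 / 3)
        assert W[0, 2] == pytest.approx(1 / 3)

    def test_rows_sum_to_one_and_zero_diagonal(self, colony150):
        W = signal_weights(colony150, 0.4)
        assert np.allclose(W.sum(axis=1), 1.0)
        assert np.allclose(np.diag(W), 0.0)
        assert (W >= 0).all()

    def test_uniform_limit_as_q_to_one(self):
        rng = np.random.default_rng(0)
        t = _tissue_from(rng.random((12, 2)) * 3)
        W = signal_weights(t, 1 - 1e-9)
        off = W[~np.eye(12, dtype=bool)]
        assert np.allclose(off, 1 / 11, atol=1e-6)

    def test_nearest_neighbour_limit_as_q_to_zero(self, colony150):
        # row mass concentrates on the nearest cell(s); near-ties may share it
        W = signal_weights(colony150, 1e-12)
        top3 = np.sort(W, axis=1)[:, -3:].sum(axis=1)
        assert top3.min() > 0.9  # ties among equidistant nearest cells share it

    def test_weights_non_increasing_in_distance(self):
        t = _tissue_from([[0, 0], [1, 0], [2.2, 0], [3.1, 0]])
        W = signal_weights(t, 0.6)
        row = W[0, 1:]
        assert np.all(np.diff(row) <= 1e-12)

    def test_single_cell_fails(self):
        t = _tissue_from([[0.0, 0.0]])
        with pytest.raises(ValueError):
            signal_weights(t, 0.5)


class TestClassifyFates:
    @pytest.mark.parametrize("u,v,expected", [(1.0, 0.01, 0), (0.01, 1.0, 1)])
    def test_examples(self, u, v, expected):
        assert classify_fates(u, v) == expected

    def test_tie_is_unresolved(self):
        with pytest.raises(UnresolvedFateError):
            classify_fates(0.5, 0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_fates(-0.1, 0.5)


class TestBalancedFilter:
    @pytest.mark.parametrize("n1,keep", [(101, False), (100, True), (75, True)])
    def test_two_thirds_rule_is_strict(self, n1, keep):
        fates = np.array([1] * n1 + [0] * (150 - n1))
        t = _tissue_from(np.random.default_rng(0).random((150, 2)), fates=fates)
        assert balanced_filter(t) is keep


class TestFateDynamics:
    def test_checkerboard_regime_negative_moran(self, checkerboard150):
        from fatepattern.cellgraph import build_graph
        from fatepattern.spatialstats import moran_index
        g = build_graph(checkerboard150)
        assert moran_index(g, checkerboard150.fates).I < 0

    def test_engulfing_regime(self, engulfing150):
        from fatepattern.cellgraph import build_graph
        from fatepattern.spatialstats import moran_index, pcf
        g = build_graph(engulfing150)
        assert moran_index(g, engulfing150.fates).I > 0.5
        r = pcf(engulfing150, engulfing150.fates)
        # the rim type is enriched at the largest pair distances
        last = max(i for i in range(20) if np.isfinite(r.rho_u[i]) or np.isfinite(r.rho_v[i]))
        rim_rho = np.nanmax([r.rho_u[last], r.rho_v[last]])
        assert rim_rho > 1.5

    def test_reproducible_given_seed(self, colony150):
        a = run_fate_dynamics(colony150, FateParams(q=0.4, seed=9))
        b = run_fate_dynamics(colony150, FateParams(q=0.4, seed=9))
        assert np.array_equal(a.fates, b.fates)
        assert np.array_equal(a.u, b.u)

    def test_symmetric_start_flags_unresolved(self):
        # a perfectly symmetric tissue with zero initial noise stays on the
        # symmetric branch; classification must flag it, not invent fates
        square = _tissue_from([[0, 0], [1, 0], [1, 1], [0, 1]])
        with pytest.raises(UnresolvedFateError):
            run_fate_dynamics(square, FateParams(q=0.3, seed=0, init_band=0.0))

    def test_fates_binary_and_complete(self, checkerboard150):
        assert set(np.unique(checkerboard150.fates)) <= {0, 1}
        assert len(checkerboard150.fates) == checkerboard150.n_cells


class TestRecipes:
    def test_recipe_c_structure(self):
        tissues = simulate_dataset("C", seed=3, n_replicates=2)
        assert len(tissues) == 18
        qs = sorted({t.q for t in tissues})
        assert qs == pytest.approx([0.1 * k for k in range(1, 10)])
        assert all(t.dim == 2 for t in tissues)

    def test_recipe_a_size_and_filter(self):
        tissues = simulate_dataset("A", seed=4, n_replicates=12)
        assert tissues, "at least one colony passes the balance filter"
        assert all(t.n_cells == 150 for t in tissues)
        assert all(balanced_filter(t) for t in tissues)
        assert all(0 < t.q < 1 for t in tissues)

    def test_unknown_recipe(self):
        with pytest.raises(ValueError, match="unknown recipe"):
            simulate_dataset("E", seed=0)
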
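import numpy as np
import pytest

from fatepattern import tissue_sim as ts


@pytest.fixture(scope="session")
def colony150():
    """A grown 2D colony of exactly 150 cells (growth phase only)."""
    return ts.grow_tissue(
        ts.GrowthParams(dim=2, t_growth=30, n_steps=6000, target_cells=150, seed=5))


@pytest.fixture(scope="session")
def organoid3d():
    """A grown 3D organoid (~330 cells, growth phase only)."""
    return ts.grow_tissue(ts.GrowthParams(dim=3, t_growth=25, n_steps=6000, seed=42))


@pytest.fixture(scope="session")
def checkerboard150(colony150):
    """Fate pattern at low dispersion (q=0.05): checkerboard regime."""
    return ts.run_fate_dynamics(colony150, ts.FateParams(q=0.05, seed=3))


@pytest.fixture(scope="session")
def engulfing150(colony150):
    """Fate pattern at high dispersion (q=0.95): engulfing regime."""
    return ts.run_fate_dynamics(colony150, ts.FateParams(q=0.95, seed=3))


def random_tissue(rng: np.random.Generator, n: int = 40, dim: int = 2) -> ts.Tissue:
    """Random point-cloud tissue with random binary fates (test helper)."""
    pos = rng.random((n, dim)) * 5.0
    fates = rng.integers(0, 2, n)
    if fates.min() == fates.max():  # both types present
        fates[0] = 1 - fates[0]
    return ts.Tissue(pos=pos, radii=np.full(n, 0.1), dim=dim,
                     fates=fates, q=None)
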
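import numpy as np
import pytest

import pgfinfer as pg

TELEGRAPH_THETA = np.array([10.0, 1.0, 1.0])  # (rho, s_on, s_off), d = 1


@pytest.fixture(scope="session")
def telegraph_model():
    return pg.make_telegraph(10.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def refractory_model():
    return pg.make_refractory(1.0, 1.0, 1.0, 20.0, 1.0)


@pytest.fixture(scope="session")
def steady_counts(telegraph_model):
    """2000-cell steady-state SSA sample from telegraph (10, 1, 1)."""
    return pg.simulate_snapshots(pg.SimProtocol(telegraph_model, n_c=2000, seed=42))


@pytest.fixture(scope="session")
def time_counts(telegraph_model):
    """Time-resolved snapshots, 12 times on (0, 6], 500 cells each."""
    times = tuple(np.linspace(0.5, 6.0, 12))
    return pg.simulate_snapshots(
        pg.SimProtocol(telegraph_model, n_c=500, times=times, seed=42)
    )


def inject_exact_epgf(data, grid, family, theta, times=None):
    """Replace a dataset's cached empirical PGF on a grid with the exact
    model PGF — the zero-loss fixed point of the objectives."""
    z = grid.nodes[:, 0]
    if times is None:
        data._epgf_cache = {grid.key() + (0,): family.steady_pgf(theta, z)}
    else:
        vals = family.time_pgf(theta, z, times)
        data._epgf_cache = {
            grid.key() + (j,): vals[j] for j in range(len(times))
        }
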
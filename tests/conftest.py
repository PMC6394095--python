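import numpy as np
import pytest

from regscape.grn import EnvSignal, FitnessConstants, ParamSet
from regscape.landscape import (DEFAULT_RANGES, GridConfig, Landscape,
                                build_grid, complete_network)


def random_paramsets(n: int, seed: int) -> list[ParamSet]:
    """Random parameter sets log-uniform over the default ranges."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        vals = [np.exp(rng.uniform(np.log(r.min), np.log(r.max)))
                for r in DEFAULT_RANGES]
        out.append(ParamSet.from_evolvable(*vals))
    return out


@pytest.fixture(scope="session")
def tiny_grid_landscape():
    """Six evolvable parameters, 5 levels each, fully connected: small enough
    to enumerate all 5**6 genotypes."""
    grid = build_grid(GridConfig(n_levels=5, seed=11))
    nets = [complete_network(5) for _ in range(6)]
    return Landscape(networks=nets, grid=grid)


@pytest.fixture(scope="session")
def default_grid_landscape():
    """Default ranges on a reduced grid (200 levels, K=10) for fast walks."""
    grid = build_grid(GridConfig(n_levels=200, seed=3))
    return Landscape.from_grn(grid, K_conn=10, sigma=4.0, seed=3)


@pytest.fixture(scope="session")
def single_peak_toy():
    from regscape.fixtures import make_toy_fixture
    return make_toy_fixture("single_peak", (5, 5))


@pytest.fixture(scope="session")
def two_peak_toy():
    """Two peaks with nearest-index moves only: some starts are trapped."""
    from regscape.fixtures import make_toy_fixture
    return make_toy_fixture("two_peak", (5, 5), complete=False)
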
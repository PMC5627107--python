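import numpy as np
import pytest

import fpnash as fp


@pytest.fixture(scope="session")
def huber():
    return fp.load_scenario("huber-135")


@pytest.fixture(scope="session")
def coarse_grid():
    """Small grid on the huber domain, cheap enough for FD oracles."""
    return fp.build_grid([(-3, 3), (-3, 3)], 8, 3.0, 8)


@pytest.fixture(scope="session")
def benchmark_grid(huber):
    return huber.build_grid()


def random_admissible(grid, rng, scale=1.0):
    """Random control pinned to zero at both endpoints."""
    u = np.zeros((grid.n_steps + 1, 2))
    u[1:-1] = rng.uniform(-scale, scale, (grid.n_steps - 1, 2))
    return u
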
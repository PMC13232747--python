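import numpy as np
import pytest

from groupgames import PayoffMatrix, SimulationConfig, generate_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """Fixed 4x4 matrix with distinct entries (no degenerate pairs)."""
    return PayoffMatrix(
        np.array(
            [
                [1.0, 0.0, 2.0, -1.0],
                [0.5, -0.5, 1.5, 0.25],
                [-2.0, 3.0, 0.75, -0.25],
                [1.25, -1.5, 0.125, 2.5],
            ]
        )
    )


@pytest.fixture
def gauss200():
    return generate_matrix(200, 0.0, 1.0, seed=7)


@pytest.fixture
def quick_config():
    return SimulationConfig(
        d=50, m=3, n=10, beta=1.0, lam=0.1, q=0.01, seed=11,
        n_events=3000, sample_every=100,
    )
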
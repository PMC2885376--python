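import numpy as np
import pytest

from miract import SimulationConfig, simulate_dataset


def random_positive_table(rng: np.random.Generator, r: int, c: int):
    """Random strictly positive table triple with generic ids."""
    values = rng.random((r, c)) + 0.05
    return values, [f"r{i}" for i in range(r)], [f"c{j}" for j in range(c)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted-signal dataset shared by coupling/ranking tests."""
    return simulate_dataset(
        SimulationConfig(g=150, n_per_group=4, m=12, n_active=2, seed=11)
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The reference recovery configuration: strong planted activity signal."""
    return simulate_dataset(SimulationConfig(seed=1))
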
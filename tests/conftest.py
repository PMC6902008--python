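import numpy as np
import pytest

from lethalscan.synthetic_population import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate gene-drop dataset shared across module tests."""
    return simulate_population(SimulationConfig(n_founders=800, n_generations=2, seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20191226)
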
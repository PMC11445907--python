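import numpy as np
import pytest

from cellfuse import SimulationParams, simulate_multimodal


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated 3-cluster dataset with 30% dropout, two small views."""
    params = SimulationParams(
        n_cells=120, n_clusters=3, dims=(40, 20), separation=4.0, dropout_rate=0.3, seed=7
    )
    return simulate_multimodal(params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
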
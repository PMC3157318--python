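import numpy as np
import pytest

from cryptdrift import SimulationParams


@pytest.fixture
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture
def tiny_params() -> SimulationParams:
    """A small lattice that keeps object-model runs cheap."""
    return SimulationParams(n_cols=4, n_rows=10, n0=4, ps=0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
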
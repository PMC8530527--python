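import numpy as np
import pytest

from reafference import SimulationGrid


@pytest.fixture
def grid20() -> SimulationGrid:
    """Canonical grid: 20 Hz stimulus at 2 kHz, 20 wavelengths."""
    return SimulationGrid(stimulus_frequency=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
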
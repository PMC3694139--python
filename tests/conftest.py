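import numpy as np
import pytest

from tumorperf.config import PhaseSepParams, SimulationConfig


@pytest.fixture
def config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def phase_params() -> PhaseSepParams:
    return PhaseSepParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
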
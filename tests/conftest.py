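import numpy as np
import pytest
from hypothesis import settings

from crpcsim import SimulationConfig

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture
def tiny_config():
    """A small, fast configuration for engine-level invariant tests."""
    cfg = SimulationConfig()
    cfg.lattice_n = 24
    cfg.initial_pc = 60
    cfg.initial_tam = 20
    cfg.timeline.castration_h = 96.0
    cfg.timeline.horizon_h = 192.0
    cfg.pc.capacity = 2000.0
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
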
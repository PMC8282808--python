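import numpy as np
import pytest

from dnascan import SimulationConfig, simulate_field


@pytest.fixture(scope="session")
def default_field():
    """All-defaults simulated field of view (scanners + free + stuck)."""
    cfg = SimulationConfig()
    loc, gt = simulate_field(cfg)
    return cfg, loc, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
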
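import numpy as np
import pytest

from rodgain.simulate import SimulationConfig, WeberGain


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def weber_config():
    """A small, fast cell: 200-rod pool with Weber gain control."""
    return SimulationConfig(n_rods=200, continuous_noise_sd=0.3,
                            gain_law=WeberGain(G_D=1.0, I_0=0.08), seed=7)
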
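import numpy as np
import pytest

from ionpull import SimConfig


@pytest.fixture
def sim():
    """Default Brownian settings with a fixed seed."""
    return SimConfig(seed=7, temperature=300.0, diffusion=0.2, timestep=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
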
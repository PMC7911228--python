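import numpy as np
import pytest
from hypothesis import settings

from snnlab import LIFParams

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def lif_defaults() -> LIFParams:
    """The default membrane constants (tau_m=10 ms, C_m=250 pF, E_L=-70 mV,
    V_th=-55 mV, V_reset=-70 mV) used throughout the experiments."""
    return LIFParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
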
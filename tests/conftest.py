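import numpy as np
import pytest

from crcdyn import default_parameters


@pytest.fixture
def app1i_params():
    """Tumor-free-attractor therapy setting (triple therapy, g2=0.2)."""
    return default_parameters(g2=0.2, u1=0.2, u2=0.4, u3=0.5)


@pytest.fixture
def fig2_params():
    """Coexistence-attractor setting (weak chemo, g2=0.6)."""
    return default_parameters(g2=0.6, u1=0.3, u2=0.2, u3=0.01)


@pytest.fixture
def app3_params():
    """Extended-model setting with the three extra recruitment channels."""
    return default_parameters(g2=0.2, u1=0.2, u2=0.4, u3=0.5,
                              g5=0.1, g6=0.15, g7=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
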
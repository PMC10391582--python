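import numpy as np
import pytest

from engramsim.config import NetworkConfig, PlasticityParams, STPParams


@pytest.fixture
def tiny_config():
    """Small circuit for structural tests (fast to build)."""
    return NetworkConfig(
        nE=40, nI=8, C=0.3, n_engrams=2, engram_size=10, seed=42
    )


@pytest.fixture
def default_layout_config():
    """The full-scale layout (2000 E / 400 I, 10 engrams of 200)."""
    return NetworkConfig(seed=7)


@pytest.fixture
def stp_params():
    return STPParams(U=0.2, tau_F=1500.0, tau_D=200.0)


@pytest.fixture
def plast_params():
    return PlasticityParams(
        A=1e-2, B=1e-2, beta=0.05, w_tilde=0.5, delta1=1e-4,
        tau_stdp=20.0, tau_stdp_slow=100.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
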
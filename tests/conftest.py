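import numpy as np
import pytest

from afshear.synthetic import make_dma_protocol, simulate_response
from afshear.types import Geometry, ViscoParams


@pytest.fixture(scope="session")
def zener_params() -> ViscoParams:
    """Single-branch solid used as the closed-form oracle throughout."""
    return ViscoParams(g_eq_kpa=50.0, branches=((30.0, 10.0),), noise_sd_n=0.0)


@pytest.fixture(scope="session")
def zener_dma_record(zener_params):
    """Noise-free 10%-strain dynamic sweep of the oracle solid."""
    protocol = make_dma_protocol(10.0)
    return simulate_response(zener_params, protocol, Geometry())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
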
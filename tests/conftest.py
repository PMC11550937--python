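import numpy as np
import pytest

from phagekit import CocultureParams


@pytest.fixture
def hourly_grid():
    return np.arange(0.0, 25.0)


@pytest.fixture
def default_params():
    """Reference co-culture: fast-growing culture, moderately lytic phage."""
    return CocultureParams(
        r=0.8, K=1e9, delta=1e-9, tau=0.5, beta=50.0, lam=0.01,
        mu_res=0.0, od_per_cell=1e-9, noise_sd=0.0, S0=1e6, P0=1e6,
    )
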
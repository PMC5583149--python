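import numpy as np
import pytest

from dnfip import FieldGrid, KernelParams, TransferParams, tactile_preset


@pytest.fixture
def grid100():
    return FieldGrid(n_sites=100, domain_extent=360.0, periodic=True)


@pytest.fixture
def kernel_params():
    """Reference Mexican-hat parametrization (strengths 14/7, widths 2/6)."""
    return KernelParams(c_exc=14.0, sigma_exc=2.0, c_inh=7.0, sigma_inh=6.0)


@pytest.fixture
def preset():
    return tactile_preset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
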
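import pytest

from tadsim.design import default_design
from tadsim.equilibrium import calibrate_junction
from tadsim.thermo import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def cal_params(params):
    """Junction entropy calibrated so the N=0 reference design melts at 62 C."""
    return calibrate_junction(default_design(N=0), 62.0, params)


@pytest.fixture(scope="session")
def n0_design():
    return default_design(N=0)


@pytest.fixture(scope="session")
def n2_design():
    return default_design(N=2, L=8)
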
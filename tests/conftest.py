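import numpy as np
import pytest

from cestnet import AcquisitionConfig, ExchangeScenario


@pytest.fixture
def two_site():
    return ExchangeScenario(
        p_g=0.95, p_e1=0.05, kex_ge1=100.0, w_g=8.0, w_e1=9.2,
        tau_m=8.0, j_hn=-93.0, r_ex=1.0,
    )


@pytest.fixture
def three_site():
    return ExchangeScenario(
        p_g=0.90, p_e1=0.06, p_e2=0.04, kex_ge1=150.0, kex_ge2=80.0,
        w_g=8.0, w_e1=9.2, w_e2=7.1, tau_m=8.0, j_hn=-93.0, r_ex=1.0,
    )


@pytest.fixture
def single_site():
    return ExchangeScenario(w_g=8.3, tau_m=8.0, j_hn=-93.0, r_ex=1.0)


@pytest.fixture
def config():
    return AcquisitionConfig(
        b0=18.8, b1=30.0, offsets=np.linspace(6.6, 10.0, 90), t_ex=0.4
    )
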
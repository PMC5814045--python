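import numpy as np
import pytest

from sealtrend import HaulOutModel
from sealtrend.synthetic import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def haulout():
    # San Benito-like attendance: arrivals N(day 20, 6 d), 31-day residence
    return HaulOutModel(arrival_mean=20.0, arrival_sd=6.0, residence_days=31.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
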
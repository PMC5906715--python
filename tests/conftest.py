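import pytest

from condsize import (
    GW_2_2_2,
    GW_5_5_5,
    load_exvivo_bath_series,
    load_saline_conductivity_table,
)


@pytest.fixture(scope="session")
def gw555():
    return GW_5_5_5


@pytest.fixture(scope="session")
def gw222():
    return GW_2_2_2


@pytest.fixture(scope="session")
def saline_table():
    return load_saline_conductivity_table()


@pytest.fixture(scope="session")
def bath_series():
    return load_exvivo_bath_series()
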
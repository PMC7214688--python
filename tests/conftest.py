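import pytest

from myophos import MetabolicConstants, get_preset


@pytest.fixture(scope="session")
def gas_plus():
    return get_preset("GAS_plus")


@pytest.fixture(scope="session")
def pla_plus():
    return get_preset("PLA_plus")


@pytest.fixture(scope="session")
def gas_minus():
    return get_preset("GAS_minus")


@pytest.fixture(scope="session")
def mc():
    return MetabolicConstants()
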
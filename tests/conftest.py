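import pytest

from methanomars import (
    AtmosphereState,
    MaintenanceModel,
    default_species_table,
    lr1_fixture,
    mars_default_atmosphere,
)


@pytest.fixture(scope="session")
def species():
    return default_species_table()


@pytest.fixture(scope="session")
def lr1():
    return lr1_fixture()


@pytest.fixture
def mars_atm():
    """Default martian scenario: 230 K, 6 hPa, 95% CO2 / 0.145% O2 / 0.69 ppbv CH4."""
    return mars_default_atmosphere(230.0, 6.0)


@pytest.fixture
def reference_atm():
    """Reference-condition scenario (298.15 K, 1 atm) with martian composition."""
    return AtmosphereState(
        T=298.15, P_atm=1.0, mix={"CO2": 0.95, "O2": 0.00145, "CH4": 0.69e-9}
    )


@pytest.fixture(scope="session")
def maintenance():
    return MaintenanceModel()
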
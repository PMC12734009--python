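import pytest

from rasctl import growth_value, reference, thermo_energy


@pytest.fixture(scope="session")
def plant():
    return thermo_energy.DEFAULT_PLANT


@pytest.fixture(scope="session")
def growth():
    return growth_value.DEFAULT_GROWTH


@pytest.fixture(scope="session")
def value_params():
    """Cycle-value model calibrated on the two ambient-8 anchor rows."""
    return growth_value.default_value_params()


@pytest.fixture(scope="session")
def scenario_tables():
    """All three published scenario sweeps, keyed by ambient temperature."""
    return {amb: reference.scenario_table(amb) for amb in reference.AMBIENTS}
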
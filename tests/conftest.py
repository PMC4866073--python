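import pytest

from barcodegap.synthetic_data import preset_scenarios, simulate_genus


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios(seed=11)


@pytest.fixture(scope="session")
def gentiana_like(presets):
    return simulate_genus(presets["gentiana-like"])


@pytest.fixture(scope="session")
def lonicera_like(presets):
    return simulate_genus(presets["lonicera-like"])


@pytest.fixture(scope="session")
def salix_like(presets):
    return simulate_genus(presets["salix-like"])


@pytest.fixture(scope="session")
def acer_like(presets):
    return simulate_genus(presets["acer-like"])
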
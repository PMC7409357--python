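import pytest

from btdflux import (
    Condition,
    btd_core_model,
    condition_presets,
    reference_state,
)
from btdflux.model import apply_condition


@pytest.fixture(scope="session")
def btd_core():
    return btd_core_model()


@pytest.fixture(scope="session")
def presets(btd_core):
    # the toy preset scale: -10 for the 6-carbon source
    return {c.name: c for c in condition_presets(btd_core, glucose_uptake=-10.0)}


@pytest.fixture(scope="session")
def glucose(presets):
    return presets["glucose"]


@pytest.fixture(scope="session")
def glucose_model(btd_core, glucose):
    return apply_condition(btd_core, glucose)


@pytest.fixture(scope="session")
def glucose_reference(glucose_model):
    return reference_state(glucose_model)


@pytest.fixture(scope="session")
def drain_model():
    return btd_core_model(with_futile_drain=True)


@pytest.fixture(scope="session")
def microaerobic():
    """Oxygen-limited glucose medium used by the strain-design tests."""
    return Condition(
        name="glucose_microaerobic",
        exchange_bounds={"EX_glc": (-10.0, 1000.0), "EX_o2": (-9.0, 1000.0)},
        carbon_source="EX_glc",
        carbon_atoms=6,
        carbon_exchanges=("EX_glc", "EX_glyc"),
    )
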
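import numpy as np
import pytest

from spere import (
    InstrumentModel,
    build_database,
    get_material,
    wavelength_grid,
)


@pytest.fixture(scope="session")
def polystyrene():
    return get_material("polystyrene")


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def silica():
    return get_material("silica")


@pytest.fixture(scope="session")
def instrument_grid():
    """Default instrument wavelength grid: 450-700 nm at 0.6-nm sampling."""
    return wavelength_grid(450.0, 700.0, 0.6)


@pytest.fixture(scope="session")
def ps_db_3um(polystyrene, water, instrument_grid):
    """Narrow polystyrene database around 3 um at the paper's 0.1-nm step."""
    return build_database(2990.0, 3010.0, 0.1, polystyrene, water, instrument_grid)


@pytest.fixture(scope="session")
def silica_db_4um(silica, water, instrument_grid):
    """Silica database around the 4-um precision sphere, 0.1-nm step."""
    return build_database(3950.0, 4050.0, 0.1, silica, water, instrument_grid)


@pytest.fixture()
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180929)
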
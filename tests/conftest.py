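import numpy as np
import pytest

from lampspec import (
    assemble_system,
    build_illumination_matrix,
    channel_sensitivity,
    default_panel,
    default_qe,
    make_bands,
    make_grid,
    make_temperature_sequence,
)


@pytest.fixture(scope="session")
def default_grid():
    return make_grid(400, 700, 10)


@pytest.fixture(scope="session")
def default_temps():
    return make_temperature_sequence(2450, 3400, 50)


@pytest.fixture(scope="session")
def qe():
    return default_qe()


@pytest.fixture(scope="session")
def illumination(default_grid, default_temps):
    return build_illumination_matrix(default_grid, default_temps)


@pytest.fixture(scope="session")
def default_system(illumination, default_grid, qe):
    bands = make_bands(400, 700, 3)
    sens = [channel_sensitivity(qe, band, default_grid) for band in bands]
    return assemble_system(illumination, sens)


@pytest.fixture(scope="session")
def panel(default_grid):
    return default_panel(0, default_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
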
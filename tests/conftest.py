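import numpy as np
import pytest

from tjumpxtal.core_model import UnitCell
from tjumpxtal.synthetic_data import (
    SyntheticSpec,
    make_toy_model,
    simulate_tjump_dataset,
)


@pytest.fixture(scope="session")
def default_spec():
    """Reference study conditions: f = 0.10, 0.5 A loop shift, 2% noise."""
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def tjump_data(default_spec):
    return simulate_tjump_dataset(default_spec)


@pytest.fixture(scope="session")
def noise_free_data():
    spec = SyntheticSpec(noise_frac=0.0, seed=11)
    return simulate_tjump_dataset(spec)


@pytest.fixture(scope="session")
def toy_models():
    spec = SyntheticSpec(seed=11)
    return make_toy_model(spec)


@pytest.fixture
def small_cell():
    return UnitCell(10.0, 10.0, 10.0)
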
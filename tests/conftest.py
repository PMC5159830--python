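import numpy as np
import pytest

from perigrid import (
    GridLayout,
    islet_nadph_population_spec,
    make_grid_layout,
    nadph_reference_protocol,
    windows_from_protocol,
)


@pytest.fixture
def layout() -> GridLayout:
    return make_grid_layout()


@pytest.fixture
def small_layout() -> GridLayout:
    return make_grid_layout(150.0, 4, 4)


@pytest.fixture
def nadph_protocol():
    return nadph_reference_protocol()


@pytest.fixture
def nadph_windows(nadph_protocol):
    return windows_from_protocol(nadph_protocol)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def default_spec():
    return islet_nadph_population_spec()
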
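import numpy as np
import pytest

from sproutfield.grid import GridSpec, ScalarField
from sproutfield.fixtures import make_fixture


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec(24, 20, 1.5, origin=(0.0, 0.0))


@pytest.fixture
def unit_grid() -> GridSpec:
    return GridSpec(32, 32, 1.0)


@pytest.fixture
def random_smooth(unit_grid) -> ScalarField:
    return make_fixture("random_smooth", unit_grid, seed=42)
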
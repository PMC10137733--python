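import numpy as np
import pytest

from bayescell import Grid1D, GridDensity1D, SensingModel, normalize
from bayescell.fixtures import gaussian_density


@pytest.fixture
def unit_gaussian():
    return gaussian_density(0.0, 1.0, -8.0, 8.0, 2001)


@pytest.fixture
def fig2_off_model():
    """Canonical sensor-OFF model: b=2, g=0, Xbar=2."""
    return SensingModel(b=2.0, g=0.0, x_bar=2.0, domain=(0.0, 33.3))


@pytest.fixture
def fig2_on_model():
    """Canonical sensor-ON model: b=2, g=1, Xbar=2."""
    return SensingModel(b=2.0, g=1.0, x_bar=2.0, domain=(0.05, 6.0))


@pytest.fixture
def uniform_01():
    grid = Grid1D(0.0, 1.0, 101)
    return normalize(GridDensity1D(grid, np.ones(101)))
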
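import numpy as np
import pytest

from pinehab.grids import Raster, RasterHeader
from pinehab.membership import MembershipParams


@pytest.fixture
def header10():
    return RasterHeader(n_cols=10, n_rows=10, x_origin=0.0, y_origin=0.0, cell_size=1.0)


@pytest.fixture
def random_raster(header10):
    rng = np.random.default_rng(42)
    return Raster(header10, rng.uniform(0, 100, (10, 10)))


@pytest.fixture
def feb_temperature_params():
    """Published February-temperature K-t fit."""
    return MembershipParams(family="kt", a=-42.4, b=5.0, c=8.0, d=33.6, k=13.0)


@pytest.fixture
def april_precip_params():
    """Published April-precipitation K-t fit."""
    return MembershipParams(family="kt", a=-63.9, b=98.8, c=113.8, d=191.3, k=1.62)
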
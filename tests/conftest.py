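import numpy as np
import pytest

import esvdyn as e


@pytest.fixture(scope="session")
def cfg():
    """Default-size synthetic study area (64x64, 2000-2020)."""
    return e.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def landscape_pair(cfg):
    """Two consecutive synthetic years."""
    return e.generate_landscape(cfg, 2000), e.generate_landscape(cfg, 2001)


@pytest.fixture(scope="session")
def landscape(landscape_pair):
    return landscape_pair[0]


@pytest.fixture(scope="session")
def drivers(cfg, landscape):
    return e.generate_drivers(cfg, landscape)


@pytest.fixture(scope="session")
def value_table():
    return e.build_value_table()


@pytest.fixture()
def toy_grid():
    """Hand-sized grid helper."""
    def make(codes, cell_area=1.0):
        return e.LandUseGrid(np.asarray(codes, dtype=np.int64),
                             cell_area=cell_area)
    return make
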
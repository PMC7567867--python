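import logging

import numpy as np
import pytest

import densfunc as df

# descriptor-margin warnings are expected for deliberately tight test grids
logging.getLogger("densfunc.potential").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def water():
    return df.toy_water()


@pytest.fixture(scope="session")
def ethanol():
    return df.toy_ethanol()


@pytest.fixture(scope="session")
def small_grid():
    """Modest cubic grid large enough for toy-water with descriptor margin."""
    return df.GridSpec.centered(9.5, 32)


@pytest.fixture(scope="session")
def small_basis(small_grid):
    return df.FourierBasisSpec(per_dim=7, box_length=small_grid.box_length)


@pytest.fixture(scope="session")
def water_dataset(water):
    """Sixty toy-water records with bond-aware densities (session-cached)."""
    return df.make_dataset(water, 60, density_mode="bonded", seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
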
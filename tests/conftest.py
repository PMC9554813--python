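import numpy as np
import pytest

from oamrecon import (AcousticConfig, GridSpec, TransducerGeometry,
                      build_model, make_virtual_elements, simulate_tir)


@pytest.fixture(scope="session")
def geom():
    return TransducerGeometry()


@pytest.fixture(scope="session")
def acfg():
    return AcousticConfig()


@pytest.fixture(scope="session")
def elements(geom):
    return make_virtual_elements(geom)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse TIR grid used by operator-level tests: 11x11 lateral offsets
    (20 um), 21 depth planes at 150 um spanning +/-1.5 mm."""
    return GridSpec(nx=11, ny=11, nz=21, dz=150e-6, lateral_radius=0.11e-3)


@pytest.fixture(scope="session")
def small_tir(geom, acfg, small_grid):
    return simulate_tir(geom, small_grid, acfg)


@pytest.fixture(scope="session")
def small_model(small_tir):
    return build_model(small_tir)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
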
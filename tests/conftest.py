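import numpy as np
import pytest

from ulfmt import (
    AcquisitionSim,
    SequenceProtocol,
    TissueParams,
    default_vial_phantom,
    load_presets,
)


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def protocol(presets):
    return presets.protocol


@pytest.fixture(scope="session")
def single_pool():
    """Single-pool reference material (no bound pool)."""
    return TissueParams(t1_free=500.0, t2_free=100.0, bound_fraction=0.0, label="single")


@pytest.fixture(scope="session")
def wm_like():
    """White-matter-like two-pool material."""
    return TissueParams(
        t1_free=350.0,
        t2_free=90.0,
        bound_fraction=0.10,
        exchange_rate=25.0,
        t1_bound=300.0,
        t2_bound=10.0,
        label="wm_like",
    )


@pytest.fixture(scope="session")
def small_vial_phantom(presets):
    """Six-vial phantom on a coarse grid to keep voxel counts small."""
    return default_vial_phantom(
        tissues=presets.tissues, grid=(30, 36, 8), voxel=(6.0, 6.0, 25.0),
        vial_radius_mm=18.0, vial_height_mm=120.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
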
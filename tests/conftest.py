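import numpy as np
import pytest

import fmtomo
from fmtomo.forward import AcquisitionGeometry, DiffusionSolver, simulate_measurements


@pytest.fixture(scope="session")
def demo_phantom():
    """Default torso phantom with a 2-mm spherical tumor."""
    return fmtomo.make_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """Coarser, cheaper phantom for fast forward-model tests."""
    return fmtomo.make_phantom(
        shape=(24, 24, 36), voxel_size=0.5, tumor_center=(7.5, 6.0, 11.0),
        tumor_radius=1.5,
    )


@pytest.fixture(scope="session")
def small_solver(small_phantom):
    vol, _ = small_phantom
    return DiffusionSolver.cached(vol)


@pytest.fixture(scope="session")
def small_geometry(small_phantom):
    vol, _ = small_phantom
    return AcquisitionGeometry.auto(vol, n_detectors_transverse=3, n_detectors_axial=5)


@pytest.fixture(scope="session")
def small_measurements(small_phantom, small_geometry):
    vol, src = small_phantom
    return simulate_measurements(vol, src, small_geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
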
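import numpy as np
import pytest
from hypothesis import settings

from octflow.geometry import ScanGeometry
from octflow.reconstruct import BeamModel

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def instrument_geometry():
    """The acquisition geometry of the DLS/PIV measurements."""
    return ScanGeometry()


@pytest.fixture
def small_geometry():
    """A desk-scale grid for simulator-driven tests."""
    return ScanGeometry(n_lateral=16, n_axial=12, n_frames=300)


@pytest.fixture
def focused_beam(small_geometry):
    z_mid = small_geometry.z_physical_um[-1] / 2.0
    return BeamModel(w0=6.0, z0=z_mid, z_R=167.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
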
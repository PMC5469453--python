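import numpy as np
import pytest

from aneurob.core_mesh import REGION_PARENT, REGION_SAC
from aneurob.synthetic_data import (
    IdealizedGeometrySpec,
    build_idealized_aneurysm,
    strip_mesh,
    tube_surface_mesh,
)


@pytest.fixture(scope="session")
def ideal_spec():
    return IdealizedGeometrySpec(sac_radius=2.0, neck_radius=2.0,
                                 edge_length=0.35)


@pytest.fixture(scope="session")
def ideal_meshes(ideal_spec):
    return build_idealized_aneurysm(ideal_spec)


@pytest.fixture(scope="session")
def ideal_surface(ideal_meshes):
    return ideal_meshes[0]


@pytest.fixture(scope="session")
def ideal_volume(ideal_meshes):
    return ideal_meshes[1]


@pytest.fixture(scope="session")
def strip500():
    """Flat 10 x 4 mm strip of 500 equal-area sac faces."""
    mesh = strip_mesh(10.0, 4.0, 0.4)
    assert mesh.n_faces == 500
    return mesh


@pytest.fixture(scope="session")
def tube_wall():
    """Open cylinder wall (R = 2 mm, L = 30 mm), parent-labeled."""
    return tube_surface_mesh(2.0, 30.0, 0.4, region=REGION_PARENT)


@pytest.fixture(scope="session")
def tube_sac():
    """Cylinder wall treated entirely as sac (for Poiseuille WSS checks)."""
    return tube_surface_mesh(2.0, 10.0, 0.2, region=REGION_SAC)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
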
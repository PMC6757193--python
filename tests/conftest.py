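import numpy as np
import pytest

from tmjsim.fem import FemBody, MooneyRivlinMaterial
from tmjsim.mesh_io import TetMesh, TriMesh


@pytest.fixture
def regular_tet():
    """Unit-edge regular tetrahedron."""
    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ]
    )
    return TetMesh(nodes, [[0, 1, 2, 3]])


@pytest.fixture
def corner_tet():
    """Right-angle corner tet with unit legs."""
    return TetMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
                   [[0, 1, 2, 3]])


@pytest.fixture
def mm_tet_body():
    """Single-tet FEM body at millimetre scale with default disk material."""
    nodes = 1e-3 * np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mesh = TetMesh(nodes, [[0, 1, 2, 3]])
    return FemBody("tet", mesh, MooneyRivlinMaterial(), total_mass=1e-6)


@pytest.fixture
def unit_square_plate():
    """Two-triangle unit plate in the z=0 plane, normals +z; metres."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    return TriMesh(v, [[0, 1, 2], [0, 2, 3]])


@pytest.fixture(scope="session")
def anatomy():
    """Shared default synthetic anatomy (expensive to build)."""
    from tmjsim.synthetic import generate_anatomy

    return generate_anatomy()
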
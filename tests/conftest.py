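import numpy as np
import pytest

from erodesim import TetMesh, generate_cylinder_mesh

UNIT_TET_NODES = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


@pytest.fixture
def unit_tet_mesh():
    return TetMesh(nodes=UNIT_TET_NODES, elements=np.array([[0, 1, 2, 3]]))


@pytest.fixture
def two_tet_mesh():
    """Two tetrahedra sharing the face (1, 2, 3)."""
    nodes = np.vstack([UNIT_TET_NODES, [[1.0, 1.0, 1.0]]])
    return TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))


@pytest.fixture(scope="session")
def small_cylinder():
    """384-element structured cylinder, cheap enough for brute-force oracles."""
    return generate_cylinder_mesh(2.0, 4.0, radial_divisions=2, axial_divisions=4)


@pytest.fixture(scope="session")
def medium_cylinder():
    """~6k-element cylinder used for statistical step/run tests."""
    return generate_cylinder_mesh(1.9, 50.3, radial_divisions=4, axial_divisions=16)
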
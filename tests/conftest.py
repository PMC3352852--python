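import numpy as np
import pytest

from gwrkit.mesh import TriangleMesh
from gwrkit.phantom import icosphere


@pytest.fixture(scope="session")
def ico1() -> TriangleMesh:
    """Unit icosphere, subdivision 1 (42 vertices)."""
    return icosphere(1, 1.0)


@pytest.fixture(scope="session")
def ico3_r30() -> TriangleMesh:
    """Icosphere subdivision 3, radius 30 mm (642 vertices)."""
    return icosphere(3, 30.0)


@pytest.fixture()
def tetra() -> TriangleMesh:
    """Regular unit-edge tetrahedron, outward winding."""
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(8.0)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
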
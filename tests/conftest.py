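import numpy as np
import pytest

from patchmorph.mesh import TriangleMesh
from patchmorph.simulate import SimulationSpec, make_template_mesh

CUBE_VERTICES = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
# outward-wound triangulation of the unit cube (12 faces)
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],
        [4, 5, 6], [4, 6, 7],
        [0, 1, 5], [0, 5, 4],
        [2, 3, 7], [2, 7, 6],
        [0, 4, 7], [0, 7, 3],
        [1, 2, 6], [1, 6, 5],
    ]
)


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    return TriangleMesh(CUBE_VERTICES.copy(), CUBE_FACES.copy())


@pytest.fixture
def icosphere():
    """Factory: icosphere(radius, subdivisions) -> TriangleMesh."""

    def make(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
        return make_template_mesh(
            SimulationSpec(structure="icosphere", radius=radius, subdivisions=subdivisions)
        )

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
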
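import math

import numpy as np
import pytest

from betapocket.structure_io import MolecularModel


@pytest.fixture
def tetrahedron():
    """Four unit spheres at the vertices of a regular tetrahedron of edge 2."""
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * (2.0 / (2.0 * math.sqrt(2.0)))
    return MolecularModel.from_arrays(verts, 1.0, "C", name="tetrahedron")


@pytest.fixture
def two_ball_ligand():
    """Balls r=1 at origin and r=2 at (4,0,0): enclosing sphere (2.5,0,0), R=3.5."""
    return MolecularModel.from_arrays(
        [[0, 0, 0], [4, 0, 0]], [1.0, 2.0], "C", role="ligand"
    )


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rigid_motion():
    """(rotation, translation) pairs for invariance checks."""
    return [(random_rotation(s), np.array([1.3 * s, -0.7 * s, 2.1])) for s in (1, 2)]
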
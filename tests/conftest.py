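import numpy as np
import pytest

from softcongruence.mesh_io import TriangleMesh
from softcongruence.synthetic_data import FaceSpec, generate_face


@pytest.fixture
def tetra() -> TriangleMesh:
    """Closed unit tetrahedron with outward-facing windings."""
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def small_face():
    """Coarse face bundle for fast geometric tests."""
    return generate_face(FaceSpec(ny=49, nz=61))


@pytest.fixture(scope="session")
def default_face():
    """Default-resolution face bundle (session-cached; generation is cheap,
    but several tests share it)."""
    return generate_face()


def make_plane(
    z: float,
    half: float = 10.0,
    n: int = 6,
    flip: bool = False,
) -> TriangleMesh:
    """Axis-aligned square grid in the plane at height ``z``.

    Windings give +z outward normals (``flip`` reverses them).
    """
    xs = np.linspace(-half, half, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    v = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, float(z))])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b = i * n + j, (i + 1) * n + j
            c, d = i * n + j + 1, (i + 1) * n + j + 1
            faces += [[a, b, c], [b, d, c]]
    f = np.array(faces)
    if flip:
        f = f[:, ::-1]
    return TriangleMesh(v, f)


def random_mesh(rng: np.random.Generator, n_tris: int, scale: float = 10.0):
    """A random triangle soup mesh (welded shared corners not required)."""
    v = rng.uniform(-scale, scale, size=(3 * n_tris, 3))
    f = np.arange(3 * n_tris).reshape(n_tris, 3)
    return TriangleMesh(v, f)


def random_rigid(rng: np.random.Generator):
    """Uniformly random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    from softcongruence.registration import RigidTransform

    q = rng.normal(size=4)
    r = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return RigidTransform(r, t)
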
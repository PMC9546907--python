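import numpy as np
import pytest

from haa3d.anatomical_frames import FootFrame
from haa3d.mesh_core import TriMesh, clean_mesh
from haa3d.phantom import PhantomSpec, generate_phantom
from haa3d.pipeline import measure_phantom


def make_box(dims, center=(0.0, 0.0, 0.0), n=1, name="other") -> TriMesh:
    """Watertight axis-aligned box with n x n grid faces."""
    dims = np.asarray(dims, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    lo = center - dims / 2.0
    hi = center + dims / 2.0
    verts = []
    faces = []

    def add_face(origin, e1, e2):
        base = len(np.concatenate(verts)) // 3 if verts else 0
        u = np.linspace(0.0, 1.0, n + 1)
        grid = (origin[None, None, :]
                + u[:, None, None] * e1[None, None, :]
                + u[None, :, None] * e2[None, None, :])
        pts = grid.reshape(-1, 3)
        verts.append(pts.ravel())
        for i in range(n):
            for j in range(n):
                a = base + i * (n + 1) + j
                b = a + 1
                c = a + (n + 1)
                d = c + 1
                faces.append([a, b, d])
                faces.append([a, d, c])

    ex = np.array([dims[0], 0, 0])
    ey = np.array([0, dims[1], 0])
    ez = np.array([0, 0, dims[2]])
    add_face(lo, ey, ex)                      # bottom (outward -z)
    add_face(lo + ez, ex, ey)                 # top
    add_face(lo, ex, ez)                      # y = lo
    add_face(lo + ey, ez, ex)                 # y = hi
    add_face(lo, ez, ey)                      # x = lo
    add_face(lo + ex, ey, ez)                 # x = hi
    vertices = np.concatenate(verts).reshape(-1, 3)
    return clean_mesh(vertices, np.asarray(faces), name=name)


def make_grid(nx=10, ny=10, size=100.0, z=0.0, name="ground") -> TriMesh:
    """Open planar grid mesh in the z-plane."""
    x = np.linspace(-size / 2, size / 2, nx + 1)
    y = np.linspace(-size / 2, size / 2, ny + 1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=1)
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = a + 1
            c = a + (ny + 1)
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriMesh(verts, np.asarray(faces), name)


def identity_frame(side="right") -> FootFrame:
    return FootFrame(np.zeros(3), np.array([1.0, 0, 0]),
                     np.array([0.0, 1.0, 0]) * (1 if side == "right" else -1),
                     np.array([0.0, 0, 1.0]), side)


@pytest.fixture(scope="session")
def upright_phantom():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def tilted_phantom():
    return generate_phantom(PhantomSpec(body_valgus_deg=15.0))


@pytest.fixture(scope="session")
def decomposed_phantom():
    return generate_phantom(PhantomSpec(body_valgus_deg=10.0,
                                        tuberosity_valgus_deg=5.0))


@pytest.fixture(scope="session")
def upright_angles(upright_phantom):
    return measure_phantom(upright_phantom)


@pytest.fixture(scope="session")
def tilted_angles(tilted_phantom):
    return measure_phantom(tilted_phantom)
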
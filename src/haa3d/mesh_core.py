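"""Triangle-mesh ingestion, validation and geometric primitives.

All coordinates are millimetres.  STL files carry no unit information; a
foot-sized bounding box (roughly 100-350 mm) is logged at load time as a
sanity check.

The module provides the primitives every measurement technique consumes:

* :class:`TriMesh` -- validated indexed triangle surface,
* :func:`load_stl` / :func:`save_stl` -- ASCII and binary STL I/O,
* :func:`volume_centroid` -- centroid of the enclosed solid,
* :func:`extreme_point` -- directional extreme vertex with tie averaging,
* :func:`surface_quadrature` -- deterministic area-weighted surface samples,
* :func:`apply_transform` -- rigid-body motion.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: faces with area below this (mm^2) are dropped at load/validation time
DEGENERATE_AREA = 1e-12
#: vertices closer than this (mm) are merged at load time
MERGE_TOL = 1e-6
#: dot-product tie tolerance (mm) for directional extreme points
EXTREME_TIE_TOL = 1e-6

KNOWN_BONE_NAMES = ("tibia", "calcaneus", "talus", "ground", "metatarsal2", "other")

#: landmark names accepted in landmark JSON files
LANDMARK_SECOND_MET = "second_met_head_plantar"
LANDMARK_MIDDLE_FACET = "talus_middle_facet_center"
KNOWN_LANDMARKS = (LANDMARK_SECOND_MET, LANDMARK_MIDDLE_FACET)


class MeshError(Exception):
    """Base class for mesh-related failures."""


class MeshFormatError(MeshError):
    """Unreadable, truncated or malformed mesh file."""


class EmptyMeshError(MeshError):
    """No faces remain after cleaning."""


class TopologyError(MeshError):
    """Operation requires a watertight mesh but the mesh has open edges."""


@dataclass(frozen=True)
class TriMesh:
    """Triangulated surface of one bone.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    name : bone label; one of :data:`KNOWN_BONE_NAMES`
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "other"

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshFormatError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshFormatError(f"faces must be (m, 3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise MeshFormatError("non-finite vertex coordinates")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshFormatError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (mm^3)."""
        t = self.triangles() - self.vertices.mean(axis=0)
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def open_edge_count(self) -> int:
        """Number of undirected edges not shared by exactly two faces."""
        e = np.concatenate([self.faces[:, [0, 1]],
                            self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.count_nonzero(counts != 2))

    def is_watertight(self) -> bool:
        return self.n_faces > 0 and self.open_edge_count() == 0

    def with_name(self, name: str) -> "TriMesh":
        return TriMesh(self.vertices, self.faces, name)


@dataclass(frozen=True)
class SurfaceSamples:
    """Deterministic area-weighted point samples of a mesh surface.

    ``weights`` are per-point areas (mm^2) and sum to the total surface
    area of the sampled mesh.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) != len(w):
            raise ValueError("points must be (n, 3) with matching weights")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "weights", w)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def centroid(self) -> np.ndarray:
        return self.points.T @ self.weights / self.weights.sum()


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def about_axis(axis: np.ndarray, angle_deg: float,
                   center: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``center``."""
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        a = np.radians(angle_deg)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=np.float64)
        return RigidTransform(rot, c - rot @ c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# construction / validation

def clean_mesh(vertices: np.ndarray, faces: np.ndarray, name: str = "other",
               merge_tol: float = MERGE_TOL) -> TriMesh:
    """Merge near-duplicate vertices and drop degenerate faces.

    Vertices closer than ``merge_tol`` are merged (snap-to-grid strategy);
    faces with repeated indices or area below :data:`DEGENERATE_AREA` are
    removed.  The merge/drop counts are logged.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if not np.all(np.isfinite(vertices)):
        raise MeshFormatError("non-finite vertex coordinates")

    n_in = len(vertices)
    keys = np.round(vertices / merge_tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    # keep first-occurrence order so cleaning is stable across platforms
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces] if faces.size else faces.reshape(0, 3)

    merged = n_in - len(new_vertices)

    if new_faces.size:
        distinct = ((new_faces[:, 0] != new_faces[:, 1])
                    & (new_faces[:, 1] != new_faces[:, 2])
                    & (new_faces[:, 0] != new_faces[:, 2]))
        t = new_vertices[new_faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        keep = distinct & (areas >= DEGENERATE_AREA)
        dropped = int(np.count_nonzero(~keep))
        new_faces = new_faces[keep]
    else:
        dropped = 0

    if len(new_faces) == 0:
        raise EmptyMeshError(f"mesh '{name}' has no faces after cleaning")

    used = np.zeros(len(new_vertices), dtype=bool)
    used[new_faces] = True
    if not used.all():
        remap = np.cumsum(used) - 1
        new_vertices = new_vertices[used]
        new_faces = remap[new_faces]

    if merged or dropped:
        logger.info("mesh '%s': merged %d vertices, dropped %d degenerate faces",
                    name, merged, dropped)
    return TriMesh(new_vertices, new_faces, name)


# ---------------------------------------------------------------------------
# STL I/O

def _parse_ascii_stl(text: str) -> tuple[np.ndarray, np.ndarray]:
    tris = []
    current: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise MeshFormatError(f"malformed vertex line: {line!r}")
            current.append([float(x) for x in parts[1:]])
        elif line.startswith("endfacet"):
            if len(current) != 3:
                raise MeshFormatError("facet without exactly 3 vertices")
            tris.append(current)
            current = []
    if current:
        raise MeshFormatError("truncated ASCII STL: unterminated facet")
    if not tris:
        raise EmptyMeshError("STL file contains no facets")
    tri = np.asarray(tris, dtype=np.float64)
    verts = tri.reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return verts, faces


def _parse_binary_stl(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    if len(data) < 84:
        raise MeshFormatError("binary STL shorter than 84-byte header")
    (n,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * n
    if len(data) < expected:
        raise MeshFormatError(
            f"truncated binary STL: {len(data)} bytes, expected {expected}")
    if n == 0:
        raise EmptyMeshError("binary STL declares zero triangles")
    rec = np.frombuffer(data, dtype=np.dtype([("normal", "<f4", 3),
                                              ("v", "<f4", (3, 3)),
                                              ("attr", "<u2")]),
                        count=n, offset=84)
    verts = rec["v"].astype(np.float64).reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return verts, faces


def load_stl(path: str | Path, name: str | None = None) -> TriMesh:
    """Read an ASCII or binary STL file into a validated :class:`TriMesh`.

    Duplicate vertices within 1e-6 mm are merged and degenerate faces are
    dropped; the cleaning report is logged along with the bounding box.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    data = path.read_bytes()
    if len(data) == 0:
        raise MeshFormatError(f"empty file: {path}")

    bone = name if name is not None else path.stem
    is_ascii = False
    if data[:5] == b"solid":
        # header alone does not prove ASCII: some binary writers start with
        # "solid"; require the keyword "facet" in a decodable body
        try:
            text = data.decode("ascii")
            is_ascii = "facet" in text or "endsolid" in text
        except UnicodeDecodeError:
            is_ascii = False
    if is_ascii:
        if "facet" not in text:
            raise EmptyMeshError(f"STL file {path} has a header but no facets")
        verts, faces = _parse_ascii_stl(text)
    else:
        verts, faces = _parse_binary_stl(data)

    mesh = clean_mesh(verts, faces, name=bone)
    lo, hi = mesh.bounds()
    span = hi - lo
    logger.info("loaded '%s' from %s: %d vertices, %d faces, bbox span "
                "%.1f x %.1f x %.1f mm", bone, path.name, mesh.n_vertices,
                mesh.n_faces, *span)
    if span.max() > 400.0 or span.max() < 5.0:
        logger.warning("mesh '%s' bounding box span %.1f mm is outside the "
                       "expected foot scale (units should be mm)",
                       bone, span.max())
    return mesh


def save_stl(mesh: TriMesh, path: str | Path, binary: bool = True) -> None:
    """Write ``mesh`` to STL (binary little-endian by default, or ASCII).

    Output is byte-deterministic for identical input meshes.
    """
    path = Path(path)
    t = mesh.triangles()
    n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    if binary:
        rec = np.zeros(mesh.n_faces, dtype=np.dtype([("normal", "<f4", 3),
                                                     ("v", "<f4", (3, 3)),
                                                     ("attr", "<u2")]))
        rec["normal"] = n.astype(np.float32)
        rec["v"] = t.astype(np.float32)
        header = f"haa3d {mesh.name}".encode("ascii")[:80].ljust(80, b"\0")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(rec.tobytes())
    else:
        lines = [f"solid {mesh.name}"]
        for i in range(mesh.n_faces):
            lines.append(f"  facet normal {n[i, 0]:.9e} {n[i, 1]:.9e} {n[i, 2]:.9e}")
            lines.append("    outer loop")
            for j in range(3):
                lines.append("      vertex "
                             f"{t[i, j, 0]:.9e} {t[i, j, 1]:.9e} {t[i, j, 2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.name}\n")
        path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# landmark files

def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    """Read a landmark JSON file mapping name -> [x, y, z] (mm)."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise MeshFormatError("landmark file must contain a JSON object")
    out = {}
    for key, value in raw.items():
        p = np.asarray(value, dtype=np.float64)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise MeshFormatError(f"landmark {key!r} is not a finite 3-vector")
        if key not in KNOWN_LANDMARKS:
            logger.warning("unrecognized landmark name %r (known: %s)",
                           key, ", ".join(KNOWN_LANDMARKS))
        out[key] = p
    return out


def save_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    payload = {k: [float(x) for x in np.asarray(v)] for k, v in sorted(landmarks.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# geometric primitives

def volume_centroid(mesh: TriMesh) -> np.ndarray:
    """Centroid of the solid enclosed by a watertight mesh.

    Uses the divergence-theorem decomposition into tetrahedra against an
    interior reference point, so the result is invariant to tessellation
    refinement.  Inward-pointing normals (negative signed volume) are
    handled by sign, with a warning.
    """
    open_edges = mesh.open_edge_count()
    if open_edges:
        raise TopologyError(
            f"mesh '{mesh.name}' is not watertight: {open_edges} open edges")
    ref = mesh.vertices.mean(axis=0)
    t = mesh.triangles() - ref
    vols = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
    total = vols.sum()
    if total < 0:
        logger.warning("mesh '%s' has inward normals (volume %.3f mm^3); "
                       "orientation flipped for centroid computation",
                       mesh.name, total)
    if abs(total) < 1e-9:
        raise TopologyError(f"mesh '{mesh.name}' encloses zero volume")
    tet_centroids = t.sum(axis=1) / 4.0  # (a+b+c+0)/4 relative to ref
    return ref + tet_centroids.T @ vols / total


def extreme_point(mesh: TriMesh, direction: np.ndarray,
                  tie_tol: float = EXTREME_TIE_TOL) -> np.ndarray:
    """Vertex of ``mesh`` farthest along ``direction``.

    If several vertices tie within ``tie_tol`` mm of the maximum (common
    for flat plantar surfaces), the centroid of the tied set is returned.
    """
    d = np.asarray(direction, dtype=np.float64)
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("direction vector must be nonzero")
    d = d / nd
    if mesh.n_vertices == 0:
        raise EmptyMeshError("cannot take extreme point of an empty mesh")
    proj = mesh.vertices @ d
    tied = proj >= proj.max() - tie_tol
    return mesh.vertices[tied].mean(axis=0)


def _subdivision_depths(mesh: TriMesh, max_edge: float) -> np.ndarray:
    t = mesh.triangles()
    e = np.stack([np.linalg.norm(t[:, 1] - t[:, 0], axis=1),
                  np.linalg.norm(t[:, 2] - t[:, 1], axis=1),
                  np.linalg.norm(t[:, 0] - t[:, 2], axis=1)])
    longest = e.max(axis=0)
    n = np.ceil(longest / max_edge).astype(np.int64)
    return np.maximum(n, 1)


def surface_quadrature(mesh: TriMesh, max_edge: float = 1.0) -> SurfaceSamples:
    """Deterministic area-weighted samples of the mesh surface.

    Every triangle is uniformly subdivided (midpoint refinement) until all
    edges are at most ``max_edge`` mm; each sub-triangle contributes one
    sample at its centroid, weighted by its area.  Total weight equals the
    mesh surface area exactly, and the construction is equivariant under
    rigid transforms.
    """
    if max_edge <= 0:
        raise ValueError("max_edge must be positive")
    if mesh.n_faces == 0:
        raise EmptyMeshError("cannot sample an empty mesh")
    # uniform refinement into n^2 congruent sub-triangles; n rounded up to
    # the next power of two so the result matches recursive midpoint splits
    n_raw = _subdivision_depths(mesh, max_edge)
    n_all = 2 ** np.ceil(np.log2(n_raw)).astype(np.int64)
    areas = mesh.face_areas()
    t = mesh.triangles()

    pts_chunks = []
    w_chunks = []
    for n in np.unique(n_all):
        sel = n_all == n
        a = t[sel, 0]
        e1 = t[sel, 1] - a
        e2 = t[sel, 2] - a
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        up = ii + jj <= n - 1
        dn = ii + jj <= n - 2
        u = np.concatenate([(ii[up] + 1.0 / 3.0), (ii[dn] + 2.0 / 3.0)]) / n
        v = np.concatenate([(jj[up] + 1.0 / 3.0), (jj[dn] + 2.0 / 3.0)]) / n
        pts = (a[:, None, :]
               + e1[:, None, :] * u[None, :, None]
               + e2[:, None, :] * v[None, :, None])
        w = np.repeat(areas[sel][:, None] / (n * n), len(u), axis=1)
        pts_chunks.append(pts.reshape(-1, 3))
        w_chunks.append(w.reshape(-1))
    return SurfaceSamples(np.concatenate(pts_chunks), np.concatenate(w_chunks))


def apply_transform(mesh: TriMesh, t: RigidTransform) -> TriMesh:
    """Rigidly move a mesh (rotation then translation)."""
    return TriMesh(t.apply(mesh.vertices), mesh.faces, mesh.name)


def mirror_mesh(mesh: TriMesh, plane_y: float = 0.0) -> TriMesh:
    """Mirror about the plane ``y = plane_y``, flipping winding to keep
    normals outward."""
    v = mesh.vertices.copy()
    v[:, 1] = 2.0 * plane_y - v[:, 1]
    f = mesh.faces[:, ::-1].copy()
    return TriMesh(v, f, mesh.name)
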
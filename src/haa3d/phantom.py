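"""Synthetic foot phantom with analytically known hindfoot angles, plus a
pre/post cohort simulator.

The phantom stands in for patient weight-bearing-CT scans: every mesh is a
simple watertight solid whose expected angle under each measurement
technique is known in closed form.  Realism is deliberately sacrificed for
verifiability:

* calcaneus -- hexagonal prism (configurable length x width x height) with
  strictly vertical medial/lateral faces over its middle section, an
  elliptically rounded posterior tuberosity, and a sharp plantar apex.
  The vertical faces make the silhouette-contour technique exact under
  frontal rotation, and the apex keeps the most-plantar point a single
  stable material vertex so talocalcaneal axes rotate rigidly.
* the posterior tuberosity slab can be tilted independently of the rest of
  the bone (rotation about the longitudinal axis with a short smooth blend
  that preserves watertightness); frontal rotations about the longitudinal
  axis leave longitudinal coordinates untouched, so the posterior-box
  clipping and PCA truths are exact.
* talus -- ellipsoid whose centroid sits at a configured (medial, dorsal)
  offset from the measured calcaneal plantar point.
* tibia -- capped cylinder (radius 15, length 100 mm) above the talus.
* metatarsal head -- small sphere on the ground, 150 mm anterior of the
  plantar point at the same medio-lateral station (so the foot frame's
  anterior axis is exactly the construction x axis).
* ground -- flat slab with its top face at z = 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_core import (LANDMARK_MIDDLE_FACET, LANDMARK_SECOND_MET,
                        RigidTransform, TriMesh, extreme_point, mirror_mesh,
                        save_landmarks, save_stl)

logger = logging.getLogger(__name__)

TRUTH_TECHNIQUES = ("A", "B1", "B2", "C", "D10", "D15", "D20", "E")

#: reference pre/post-operative marginal moments (degrees) for a severe
#: flatfoot cohort, per technique: (pre_mean, pre_std, post_mean, post_std).
#: CLINICAL and RENDER are manual goniometer measurements accepted as plain
#: data columns.
REFERENCE_COHORT_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "A": (51.19, 10.27, 38.32, 10.42),
    "B1": (27.49, 10.09, 11.53, 8.90),
    "B2": (43.58, 10.10, 22.10, 11.15),
    "C": (37.94, 5.73, 26.38, 8.99),
    "D10": (16.49, 12.81, 24.40, 13.92),
    "D15": (10.06, 4.86, 10.21, 4.93),
    "D20": (9.92, 5.63, 7.42, 3.03),
    "E": (10.26, 6.74, 8.64, 6.13),
    "CLINICAL": (14.40, 4.25, 5.20, 2.53),
    "RENDER": (18.70, 5.74, 9.08, 4.85),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic foot.

    Angles are degrees, valgus positive; offsets and dimensions are mm.
    ``talus_offset`` / ``facet_offset`` are (medial, dorsal) positions of
    the talus centroid / middle-facet landmark relative to the calcaneal
    most-plantar point.
    """

    body_valgus_deg: float = 0.0
    tuberosity_valgus_deg: float = 0.0
    tibia_tilt_deg: float = 0.0
    talus_offset: tuple[float, float] = (10.0, 50.0)
    facet_offset: tuple[float, float] = (15.0, 45.0)
    calc_dims: tuple[float, float, float] = (80.0, 30.0, 45.0)
    tuberosity_fraction: float = 0.20
    side: str = "right"
    seed: int = 0
    noise_mm: float = 0.0
    # fraction of the calcaneal length (from the posterior tip) at which
    # the plantar apex sits; must stay inside the tuberosity slab
    apex_fraction: float = 0.18
    mesh_step: float = 1.1

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.calc_dims):
            raise ValueError("calc_dims must be positive")
        if not 0.0 < self.tuberosity_fraction < 0.5:
            raise ValueError("tuberosity_fraction must be in (0, 0.5)")
        if self.noise_mm < 0:
            raise ValueError("noise_mm must be non-negative")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.talus_offset[1] <= 0 or self.facet_offset[1] <= 0:
            raise ValueError("talus/facet dorsal offsets must be positive")
        if not 0.0 < self.apex_fraction < self.tuberosity_fraction:
            raise ValueError("apex_fraction must lie inside the tuberosity slab")


@dataclass(frozen=True)
class PhantomSet:
    """Generated meshes, landmarks and analytic per-technique truth."""

    meshes: dict[str, TriMesh]
    landmarks: dict[str, np.ndarray]
    truth: dict[str, float]
    spec: PhantomSpec = field(repr=False)


# ---------------------------------------------------------------------------
# mesh builders

def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    t = vertices[faces] - vertices.mean(axis=0)
    vol = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    return faces[:, ::-1] if vol < 0 else faces


def _subdivided_edge(p0: np.ndarray, p1: np.ndarray, step: float,
                     force_even: bool = False) -> np.ndarray:
    n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / step)))
    if force_even and n % 2:
        n += 1
    t = np.arange(n) / n
    return p0 + np.outer(t, p1 - p0)


def _cross_section_profile(width: float, height: float, edge_half: float,
                           inset: float, step: float) -> np.ndarray:
    """Closed CCW (medial, vertical) profile of the calcaneal cross-section.

    The section is a symmetric cross: medial/lateral faces are exactly
    vertical planes over |t| <= edge_half, joined by horizontal ledges to
    narrower dorsal and plantar blocks of half-width ``width/2 - inset``.
    Along a horizontal ledge the frontal medial coordinate drops at rate
    cos(tilt) per mm, faster than the vertical face's sin(tilt) for tilts
    below 45 deg, so the silhouette extreme points of both half-heights
    stay exactly on the vertical face planes and the contour technique
    recovers the frontal tilt exactly.  The bottom edge subdivision always
    contains the midpoint m = 0 (the plantar apex line).
    """
    w2, h2, wb = width / 2.0, height / 2.0, width / 2.0 - inset
    corners = [(wb, -h2), (wb, -edge_half), (w2, -edge_half), (w2, edge_half),
               (wb, edge_half), (wb, h2), (-wb, h2), (-wb, edge_half),
               (-w2, edge_half), (-w2, -edge_half), (-wb, -edge_half),
               (-wb, -h2)]
    pts = []
    for i, c in enumerate(corners):
        p0 = np.array(c, dtype=np.float64)
        p1 = np.array(corners[(i + 1) % len(corners)], dtype=np.float64)
        pts.append(_subdivided_edge(p0, p1, step,
                                    force_even=(i == len(corners) - 1)))
    return np.concatenate(pts)


def _tube_mesh(x_stations: np.ndarray, scales: np.ndarray,
               profile: np.ndarray, name: str) -> TriMesh:
    """Capped prism: profile rings at each x station scaled about (0, 0).

    Side quads are split into four triangles about their center point so
    the triangulation (and hence any surface sampling built on it) is
    mirror-symmetric whenever the profile is.
    """
    s_count, p_count = len(x_stations), len(profile)
    rings = np.empty((s_count, p_count, 3))
    rings[:, :, 0] = x_stations[:, None]
    rings[:, :, 1] = scales[:, None] * profile[None, :, 0]
    rings[:, :, 2] = scales[:, None] * profile[None, :, 1]
    ring_v = rings.reshape(-1, 3)

    a_idx, b_idx, faces = [], [], []
    for s in range(s_count - 1):
        a = s * p_count + np.arange(p_count)
        b = s * p_count + (np.arange(p_count) + 1) % p_count
        a_idx.append(a)
        b_idx.append(b)
    a_idx = np.concatenate(a_idx)
    b_idx = np.concatenate(b_idx)
    centers = 0.25 * (ring_v[a_idx] + ring_v[b_idx]
                      + ring_v[a_idx + p_count] + ring_v[b_idx + p_count])
    n_ring = len(ring_v)
    c_idx = n_ring + np.arange(len(centers))
    back = np.array([x_stations[0], 0.0, 0.0])
    front = np.array([x_stations[-1], 0.0, 0.0])
    vertices = np.concatenate([ring_v, centers, [back], [front]])
    i_back, i_front = len(vertices) - 2, len(vertices) - 1

    faces.append(np.stack([a_idx, b_idx, c_idx], axis=1))
    faces.append(np.stack([b_idx, b_idx + p_count, c_idx], axis=1))
    faces.append(np.stack([b_idx + p_count, a_idx + p_count, c_idx], axis=1))
    faces.append(np.stack([a_idx + p_count, a_idx, c_idx], axis=1))
    a = np.arange(p_count)
    b = (np.arange(p_count) + 1) % p_count
    faces.append(np.stack([np.full(p_count, i_back), b, a], axis=1))
    off = (s_count - 1) * p_count
    faces.append(np.stack([np.full(p_count, i_front), off + a, off + b], axis=1))
    f = np.concatenate(faces)
    return TriMesh(vertices, _orient_outward(vertices, f), name)


def _uv_sphere(center: np.ndarray, radii: np.ndarray, n_lat: int, n_lon: int,
               name: str) -> TriMesh:
    lat = np.linspace(0.0, np.pi, n_lat + 1)[1:-1]
    lon = np.linspace(0.0, 2 * np.pi, n_lon, endpoint=False)
    sin_lat, cos_lat = np.sin(lat), np.cos(lat)
    x = np.outer(cos_lat, np.ones(n_lon))
    y = np.outer(sin_lat, np.cos(lon))
    z = np.outer(sin_lat, np.sin(lon))
    ring_pts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    poles = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    unit = np.concatenate([ring_pts, poles])
    vertices = center + unit * radii
    i_top, i_bot = len(unit) - 2, len(unit) - 1

    faces = []
    rings = len(lat)
    for r in range(rings - 1):
        a = r * n_lon + np.arange(n_lon)
        b = r * n_lon + (np.arange(n_lon) + 1) % n_lon
        faces.append(np.stack([a, b, b + n_lon], axis=1))
        faces.append(np.stack([a, b + n_lon, a + n_lon], axis=1))
    a = np.arange(n_lon)
    b = (np.arange(n_lon) + 1) % n_lon
    faces.append(np.stack([np.full(n_lon, i_top), b, a], axis=1))
    off = (rings - 1) * n_lon
    faces.append(np.stack([np.full(n_lon, i_bot), off + a, off + b], axis=1))
    f = np.concatenate(faces)
    return TriMesh(vertices, _orient_outward(vertices, f), name)


def _box_mesh(lo: np.ndarray, hi: np.ndarray, name: str) -> TriMesh:
    lo = np.asarray(lo, dtype=np.float64)
    hi = np.asarray(hi, dtype=np.float64)
    corners = np.array([[lo[0], lo[1], lo[2]], [hi[0], lo[1], lo[2]],
                        [hi[0], hi[1], lo[2]], [lo[0], hi[1], lo[2]],
                        [lo[0], lo[1], hi[2]], [hi[0], lo[1], hi[2]],
                        [hi[0], hi[1], hi[2]], [lo[0], hi[1], hi[2]]])
    quads = [(0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
             (2, 3, 7, 6), (1, 2, 6, 5), (3, 0, 4, 7)]
    faces = []
    for q in quads:
        faces.append([q[0], q[1], q[2]])
        faces.append([q[0], q[2], q[3]])
    return TriMesh(corners, np.asarray(faces), name)


def _cylinder_mesh(base_center: np.ndarray, axis: np.ndarray, radius: float,
                   length: float, step: float, name: str) -> TriMesh:
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    n_around = max(12, int(np.ceil(2 * np.pi * radius / step)))
    ang = np.linspace(0.0, 2 * np.pi, n_around, endpoint=False)
    profile = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    n_along = max(2, int(np.ceil(length / step)))
    stations = np.linspace(0.0, length, n_along + 1)
    mesh = _tube_mesh(stations, np.ones(len(stations)), profile, name)
    # canonical axis is +x; rotate onto the requested axis
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, axis)
    c = float(x @ axis)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([-1.0, 1.0, -1.0])
    else:
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + k + k @ k / (1.0 + c)
    t = RigidTransform(rot, np.asarray(base_center, dtype=np.float64))
    return TriMesh(t.apply(mesh.vertices), mesh.faces, name)


# ---------------------------------------------------------------------------
# calcaneus construction

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _build_calcaneus(spec: PhantomSpec) -> TriMesh:
    length, width, height = spec.calc_dims
    edge_half = height / 3.0
    inset = 0.30 * width
    step = spec.mesh_step

    profile = _cross_section_profile(width, height, edge_half, inset, step)

    # stations: conically tapered tuberosity, then uniform spacing; the
    # apex station is inserted exactly so the plantar apex is a vertex.
    # A linear taper keeps a nonzero profile slope at the junction, so
    # taper samples never out-compete the vertical faces for silhouette
    # extremes, and the small posterior cross-sections keep the whole-bone
    # principal axes close to the body axes when the tuberosity is tilted
    round_len = spec.tuberosity_fraction * length
    apex_x = spec.apex_fraction * length
    u_round = np.linspace(0.04 * round_len, round_len, 15)
    u_straight = np.arange(round_len + step, length, step)
    stations = np.unique(np.concatenate([u_round, u_straight,
                                         [apex_x, length]]))
    scales = np.minimum(1.0, stations / round_len)

    mesh = _tube_mesh(stations, scales, profile, "calcaneus")
    v = mesh.vertices.copy()

    # plantar apex bulge: a sharply curved downward dome on the bottom face,
    # peaked at (apex_x, m = 0); curvature keeps the most-plantar vertex a
    # single stable material point under frontal rotations up to ~40 deg
    depth = 0.15 * height
    w_m = 0.067 * width
    w_x = 0.075 * length
    g_x = np.clip(1.0 - ((v[:, 0] - apex_x) / w_x) ** 2, 0.0, None)
    g_m = np.clip(1.0 - (v[:, 1] / w_m) ** 2, 0.0, None)
    g_z = np.clip((-v[:, 2] - edge_half) / (height / 2.0 - edge_half), 0.0, 1.0)
    v[:, 2] -= depth * g_x * g_m * g_z

    # independent tuberosity tilt about the longitudinal axis (x), full for
    # the posterior slab with a short smooth blend anterior of it
    tau = np.radians(spec.tuberosity_valgus_deg)
    if tau != 0.0:
        blend = 2.0
        x_tub = spec.tuberosity_fraction * length
        w = 1.0 - _smoothstep((v[:, 0] - x_tub) / blend)
        ang = tau * w
        y, z = v[:, 1].copy(), v[:, 2].copy()
        # +valgus tilts the dorsal end toward medial (+y)
        v[:, 1] = y * np.cos(ang) + z * np.sin(ang)
        v[:, 2] = -y * np.sin(ang) + z * np.cos(ang)

    beta = np.radians(spec.body_valgus_deg)
    if beta != 0.0:
        y, z = v[:, 1].copy(), v[:, 2].copy()
        v[:, 1] = y * np.cos(beta) + z * np.sin(beta)
        v[:, 2] = -y * np.sin(beta) + z * np.cos(beta)

    return TriMesh(v, mesh.faces, "calcaneus")


# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomSet:
    """Build the full phantom: five meshes, two landmarks and the analytic
    truth table.  Identical specs produce bitwise-identical output."""
    rng = np.random.default_rng(spec.seed)

    def jitter(mesh: TriMesh) -> TriMesh:
        # draw even when noise is zero so the stream layout is stable
        noise = rng.uniform(-1.0, 1.0, size=mesh.vertices.shape)
        if spec.noise_mm == 0.0:
            return mesh
        return TriMesh(mesh.vertices + spec.noise_mm * noise,
                       mesh.faces, mesh.name)

    calc = jitter(_build_calcaneus(spec))
    v = calc.vertices.copy()
    v[:, 2] -= v[:, 2].min()  # rest on the ground plane z = 0
    calc = TriMesh(v, calc.faces, "calcaneus")

    plantar = extreme_point(calc, np.array([0.0, 0.0, -1.0]))

    m_off, d_off = spec.talus_offset
    talus_center = plantar + np.array([12.0, m_off, d_off])
    talus = jitter(_uv_sphere(talus_center, np.array([20.0, 14.0, 13.0]),
                              26, 52, "talus"))

    tt = np.radians(spec.tibia_tilt_deg)
    tibia_axis = np.array([0.0, np.sin(tt), np.cos(tt)])
    tibia_base = talus_center + 25.0 * tibia_axis
    tibia = jitter(_cylinder_mesh(tibia_base, tibia_axis, 15.0, 100.0,
                                  1.4, "tibia"))

    met_plantar = np.array([plantar[0] + 150.0, plantar[1], 0.0])
    met = jitter(_uv_sphere(met_plantar + np.array([0.0, 0.0, 8.0]),
                            np.full(3, 8.0), 14, 28, "metatarsal2"))

    ground = _box_mesh([plantar[0] - 60.0, plantar[1] - 70.0, -6.0],
                       [plantar[0] + 200.0, plantar[1] + 70.0, 0.0], "ground")

    fm, fd = spec.facet_offset
    landmarks = {
        LANDMARK_SECOND_MET: met_plantar,
        LANDMARK_MIDDLE_FACET: plantar + np.array([0.0, fm, fd]),
    }

    meshes = {"tibia": tibia, "calcaneus": calc, "talus": talus,
              "ground": ground, "metatarsal2": met}

    if spec.side == "left":
        meshes = {k: mirror_mesh(m) for k, m in meshes.items()}
        landmarks = {k: p * np.array([1.0, -1.0, 1.0])
                     for k, p in landmarks.items()}

    body, tub, tib = (spec.body_valgus_deg, spec.tuberosity_valgus_deg,
                      spec.tibia_tilt_deg)
    truth = {
        "A": body - tib,
        "B1": float(np.degrees(np.arctan2(m_off, d_off))) - tib,
        "B2": float(np.degrees(np.arctan2(fm, fd))) - tib,
        "C": body - tib,
        "D10": body + tub - tib,
        "D15": body + tub - tib,
        "D20": body + tub - tib,
        "E": body + tub - tib,
    }
    return PhantomSet(meshes, landmarks, truth, spec)


def write_phantom(pset: PhantomSet, out_dir: str | Path,
                  ascii_stl: bool = False) -> list[Path]:
    """Write the phantom meshes, landmark JSON and truth JSON to a
    directory; returns the list of written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mesh in pset.meshes.items():
        path = out_dir / f"{name}.stl"
        save_stl(mesh, path, binary=not ascii_stl)
        written.append(path)
    lm_path = out_dir / "landmarks.json"
    save_landmarks(pset.landmarks, lm_path)
    written.append(lm_path)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(
        {k: round(float(v), 6) for k, v in pset.truth.items()},
        indent=2, sort_keys=True) + "\n")
    written.append(truth_path)
    return written


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(n_subjects: int,
                    technique_params: dict[str, tuple[float, float, float, float]],
                    pre_post_correlation: float = 0.7,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a subjects x techniques pre/post angle table.

    For each subject and technique, (pre, post) is drawn from a bivariate
    normal with the given marginal moments and correlation.  The paired
    pre/post correlation is an explicit parameter because paired-test power
    depends on it.  Returns a long-format table with columns
    (subject_id, session, technique, angle_deg).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not -1.0 <= pre_post_correlation <= 1.0:
        raise ValueError("pre_post_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    rho = pre_post_correlation
    rows = []
    for tech, (m1, s1, m2, s2) in technique_params.items():
        if s1 < 0 or s2 < 0:
            raise ValueError(f"negative std for technique {tech!r}")
        z = rng.standard_normal((n_subjects, 2))
        pre = m1 + s1 * z[:, 0]
        post = m2 + s2 * (rho * z[:, 0] + np.sqrt(1.0 - rho ** 2) * z[:, 1])
        for i in range(n_subjects):
            sid = f"S{i + 1:02d}"
            rows.append((sid, "pre", tech, pre[i]))
            rows.append((sid, "post", tech, post[i]))
    return pd.DataFrame(rows, columns=["subject_id", "session",
                                       "technique", "angle_deg"])
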
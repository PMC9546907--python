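"""Whole-foot anatomical frame, surface PCA frames and the signed
frontal-plane angle primitive.

Conventions
-----------
The foot frame is the right-handed triad (anterior, medial, dorsal) for a
right foot; for a left foot the medial axis is negated so that valgus is
positive on both sides.  The frontal plane is spanned by (medial, dorsal).
All principal axes are treated as undirected lines and sign-normalized
(dorsal-positive) before any angle is computed.  Signed angles are valgus
positive: the hindfoot axis tilted with its dorsal tip toward medial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh_core import SurfaceSamples, TriMesh, surface_quadrature

logger = logging.getLogger(__name__)

AXIS_LABELS = ("longitudinal", "vertical", "transverse")

#: minimum separation (mm) of the ground-projected frame landmarks
MIN_FRAME_BASELINE = 10.0


class FrameError(Exception):
    """Base class for frame-construction failures."""


class DegeneratePlaneError(FrameError):
    pass


class DegenerateFrameError(FrameError):
    pass


class RankError(FrameError):
    """Sample points do not span three dimensions."""


class ProjectionError(FrameError):
    """Vector has no usable frontal-plane component."""


@dataclass(frozen=True)
class Plane:
    """Point + upward unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        d = (points - self.point) @ self.normal
        return points - np.multiply.outer(d, self.normal)


DEFAULT_GROUND = Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))


@dataclass(frozen=True)
class FootFrame:
    """Whole-foot anatomical frame tied to the ground plane.

    ``origin`` is the ground projection of the calcaneus most-plantar
    point; the dorsal axis is the upward ground normal and the anterior
    axis lies in the ground plane.
    """

    origin: np.ndarray
    anterior: np.ndarray
    medial: np.ndarray
    dorsal: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        for attr in ("origin", "anterior", "medial", "dorsal"):
            object.__setattr__(self, attr,
                               np.asarray(getattr(self, attr), dtype=np.float64))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for a in (self.anterior, self.medial, self.dorsal):
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise DegenerateFrameError("frame axes must be unit vectors")
        if (abs(self.anterior @ self.medial) > 1e-9
                or abs(self.anterior @ self.dorsal) > 1e-9
                or abs(self.medial @ self.dorsal) > 1e-9):
            raise DegenerateFrameError("frame axes must be orthogonal")

    def to_dict(self) -> dict:
        return {
            "origin": [float(x) for x in self.origin],
            "anterior": [float(x) for x in self.anterior],
            "medial": [float(x) for x in self.medial],
            "dorsal": [float(x) for x in self.dorsal],
            "side": self.side,
        }


@dataclass(frozen=True)
class PcaFrame:
    """Centroid + variance-ordered orthonormal axes with anatomical labels."""

    centroid: np.ndarray
    axes: np.ndarray            # (3, 3), rows ordered by descending variance
    variances: np.ndarray       # (3,), mm^2
    labels: tuple[str, str, str]

    def axis(self, label: str) -> np.ndarray:
        """Axis carrying the given anatomical label."""
        return self.axes[self.labels.index(label)]

    def variance(self, label: str) -> float:
        return float(self.variances[self.labels.index(label)])


@dataclass(frozen=True)
class HaaResult:
    """One technique's signed hindfoot alignment angle (valgus positive)."""

    technique: str
    angle_deg: float
    tibia_axis_2d: np.ndarray     # unit (medial, dorsal), dorsal > 0
    hindfoot_axis_2d: np.ndarray
    provenance: dict

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return [float(x) for x in obj.ravel()]
            if isinstance(obj, (np.floating, float)):
                return float(obj)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return {
            "technique": self.technique,
            "angle_deg": round(float(self.angle_deg), 6),
            "tibia_axis_2d": [round(float(x), 9) for x in self.tibia_axis_2d],
            "hindfoot_axis_2d": [round(float(x), 9) for x in self.hindfoot_axis_2d],
            "provenance": _clean(self.provenance),
        }


# ---------------------------------------------------------------------------

def fit_ground_plane(ground: TriMesh,
                     toward: np.ndarray | None = None) -> Plane:
    """Least-squares plane through the ground-mesh vertices.

    The normal is oriented toward ``toward`` (typically the mean of the
    bone centroids, i.e. upward); with no reference it is oriented to have
    a positive z component.
    """
    v = ground.vertices
    if len(v) < 3:
        raise DegeneratePlaneError("ground mesh has fewer than 3 vertices")
    center = v.mean(axis=0)
    u, s, vt = np.linalg.svd(v - center, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegeneratePlaneError("ground vertices are collinear")
    normal = vt[2]
    if toward is not None:
        if (np.asarray(toward, dtype=np.float64) - center) @ normal < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    return Plane(center, normal)


def build_foot_frame(calc_plantar: np.ndarray, second_met_head: np.ndarray,
                     ground: Plane, side: str) -> FootFrame:
    """Construct the whole-foot frame.

    dorsal = upward ground normal; anterior = in-plane unit vector from the
    ground-projected calcaneus most-plantar point to the ground-projected
    second-metatarsal-head point; medial completes the triad and is negated
    for left feet so valgus stays positive.
    """
    origin = ground.project(np.asarray(calc_plantar, dtype=np.float64))
    ahead = ground.project(np.asarray(second_met_head, dtype=np.float64))
    baseline = ahead - origin
    dist = np.linalg.norm(baseline)
    if dist < MIN_FRAME_BASELINE:
        raise DegenerateFrameError(
            f"projected calcaneus and metatarsal points are {dist:.2f} mm "
            f"apart (need > {MIN_FRAME_BASELINE} mm)")
    anterior = baseline / dist
    dorsal = ground.normal
    medial = np.cross(dorsal, anterior)
    medial /= np.linalg.norm(medial)
    if side == "left":
        medial = -medial
    return FootFrame(origin, anterior, medial, dorsal, side)


def weighted_pca(points: np.ndarray,
                 weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of the weighted covariance of ``points``.

    Returns (centroid, axes, variances) with axes as rows ordered by
    descending variance.  Eigenvector signs are arbitrary.
    """
    points = np.asarray(points, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    w = weights / weights.sum()
    centroid = points.T @ w
    d = points - centroid
    cov = (d * w[:, None]).T @ d
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return centroid, vecs[:, order].T, vals[order]


def pca_frame(samples: SurfaceSamples, reference: FootFrame) -> PcaFrame:
    """Anatomically labelled principal-axis frame of a bone surface.

    Principal axes of the area-weighted covariance are labelled greedily
    (largest variance first) by best |cosine| alignment with the reference
    frame axes -- anterior -> longitudinal, dorsal -> vertical,
    medial -> transverse -- and sign-flipped to point along the matched
    reference axis.  A warning is logged when the resulting labels deviate
    from the usual variance ordering (longitudinal largest, vertical
    second).
    """
    if len(samples.points) < 4:
        raise RankError("need at least 4 sample points")
    centroid, axes, variances = weighted_pca(samples.points, samples.weights)
    if variances[2] < 1e-9 * max(variances[0], 1.0):
        raise RankError("sample points are coplanar")

    ref_axes = {"longitudinal": reference.anterior,
                "vertical": reference.dorsal,
                "transverse": reference.medial}
    remaining = dict(ref_axes)
    labels: list[str] = []
    oriented = axes.copy()
    for k in range(3):
        cos = {lab: float(oriented[k] @ ax) for lab, ax in remaining.items()}
        best = max(cos, key=lambda lab: abs(cos[lab]))
        if cos[best] < 0:
            oriented[k] = -oriented[k]
        labels.append(best)
        del remaining[best]

    if tuple(labels[:2]) != ("longitudinal", "vertical"):
        logger.warning(
            "PCA variance ordering %s deviates from the expected "
            "(longitudinal, vertical, transverse) pattern", tuple(labels))
    return PcaFrame(centroid, oriented, variances, tuple(labels))


def project_frontal(v: np.ndarray, frame: FootFrame) -> np.ndarray:
    """Project a 3-vector onto the frontal plane as a unit (medial, dorsal)
    pair with positive dorsal component (axes are undirected lines)."""
    v = np.asarray(v, dtype=np.float64)
    p = np.array([v @ frame.medial, v @ frame.dorsal])
    norm = np.linalg.norm(p)
    if norm < 1e-9:
        raise ProjectionError("vector has no frontal-plane component")
    p = p / norm
    if p[1] < 0:
        p = -p
    return p


def signed_haa(tibia_2d: np.ndarray, hindfoot_2d: np.ndarray) -> float:
    """Signed angle (degrees, valgus positive) between two frontal-plane
    unit vectors with positive dorsal components.

    Positive when the hindfoot vector's dorsal tip is rotated toward
    medial relative to the tibial vector.
    """
    t = np.asarray(tibia_2d, dtype=np.float64)
    h = np.asarray(hindfoot_2d, dtype=np.float64)
    return float(np.degrees(np.arctan2(h[0], h[1]) - np.arctan2(t[0], t[1])))


def tibia_vertical_axis(tibia: TriMesh, frame: FootFrame,
                        max_edge: float = 1.0,
                        samples: SurfaceSamples | None = None) -> np.ndarray:
    """Longitudinal axis of the distal tibial diaphyseal segment.

    The largest-variance principal axis of the tibial surface (the long
    axis of a diaphyseal tube), oriented dorsal-positive.  A warning is
    logged when the segment is too stubby for the axis to be reliable.
    """
    if samples is None:
        samples = surface_quadrature(tibia, max_edge)
    _, axes, variances = weighted_pca(samples.points, samples.weights)
    if variances[2] < 1e-9 * max(variances[0], 1.0):
        raise RankError("tibial surface points are coplanar")
    # extent check: diaphyseal segments should be clearly elongated
    long_extent = np.ptp(samples.points @ axes[0])
    trans_extent = max(np.ptp(samples.points @ axes[1]), 1e-9)
    if long_extent < 2.0 * trans_extent:
        logger.warning("tibial segment longitudinal extent %.1f mm is less "
                       "than twice the transverse extent %.1f mm; axis may "
                       "be unreliable", long_extent, trans_extent)
    axis = axes[0]
    if axis @ frame.dorsal < 0:
        axis = -axis
    return axis
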
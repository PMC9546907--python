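"""The six 3D hindfoot-alignment-angle measurement techniques.

Each technique maps bone meshes (realigned in the whole-foot frame) plus
optional landmarks to an :class:`~haa3d.anatomical_frames.HaaResult`:

* ``A``   -- vertical principal axis of the whole calcaneus surface,
* ``B1``  -- most-plantar calcaneal point to talus volume centroid,
* ``B2``  -- most-plantar calcaneal point to the talar middle-facet centre,
* ``C``   -- bisector of the medial and lateral silhouette contour segments,
* ``D10/D15/D20`` -- vertical axis of the posterior 10/15/20 % calcaneal slab,
* ``E``   -- as D with the slab grown until the most plantar point is inside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .anatomical_frames import (FootFrame, HaaResult, RankError, pca_frame,
                                project_frontal, signed_haa,
                                tibia_vertical_axis, weighted_pca)
from .mesh_core import (EXTREME_TIE_TOL, SurfaceSamples, TriMesh,
                        extreme_point, surface_quadrature, volume_centroid)

logger = logging.getLogger(__name__)

TECHNIQUE_ORDER = ("A", "B1", "B2", "C", "D10", "D15", "D20", "E")

#: minimum plantar-bounded box width, as a fraction of calcaneal length
MIN_E_WIDTH_FRACTION = 0.02


class TechniqueError(Exception):
    pass


class LandmarkRequiredError(TechniqueError):
    pass


class ContourError(TechniqueError):
    pass


class SlabRankError(TechniqueError):
    """Clipped slab retains too few non-coplanar samples for PCA."""


@dataclass(frozen=True)
class PosteriorBox:
    """Posterior calcaneal clipping box along the longitudinal axis."""

    axis: np.ndarray          # calcaneal longitudinal unit vector, anterior +
    posterior_limit: float    # coordinate along axis of the most posterior sample
    width: float              # box extent along axis, mm
    fraction: float           # width / total calcaneal length

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0 + 1e-9:
            raise TechniqueError(f"box fraction {self.fraction:.3f} outside (0, 1]")


def _result(technique: str, hind_axis_2d: np.ndarray, tibia_axis: np.ndarray,
            frame: FootFrame, provenance: dict) -> HaaResult:
    tibia_2d = project_frontal(tibia_axis, frame)
    angle = signed_haa(tibia_2d, hind_axis_2d)
    return HaaResult(technique, angle, tibia_2d, hind_axis_2d, provenance)


def _calc_samples(calcaneus: TriMesh, max_edge: float,
                  samples: SurfaceSamples | None) -> SurfaceSamples:
    return samples if samples is not None else surface_quadrature(calcaneus, max_edge)


# ---------------------------------------------------------------------------
# technique A

def technique_A(calcaneus: TriMesh, tibia_axis: np.ndarray, frame: FootFrame,
                max_edge: float = 1.0,
                samples: SurfaceSamples | None = None) -> HaaResult:
    """Whole-calcaneus PCA: the vertical-labelled principal axis projected
    onto the frontal plane."""
    samples = _calc_samples(calcaneus, max_edge, samples)
    pf = pca_frame(samples, frame)
    axis = pf.axis("vertical")
    hind_2d = project_frontal(axis, frame)
    return _result("A", hind_2d, tibia_axis, frame, {
        "calcaneus_vertical_axis": axis,
        "variances": pf.variances,
        "labels": list(pf.labels),
    })


# ---------------------------------------------------------------------------
# techniques B1 / B2

def technique_B1(calcaneus: TriMesh, talus: TriMesh, tibia_axis: np.ndarray,
                 frame: FootFrame) -> HaaResult:
    """Talocalcaneal axis: most plantar calcaneal point to talus centroid."""
    plantar = extreme_point(calcaneus, -frame.dorsal)
    centroid = volume_centroid(talus)
    axis = centroid - plantar
    hind_2d = project_frontal(axis, frame)
    return _result("B1", hind_2d, tibia_axis, frame, {
        "calcaneus_plantar_point": plantar,
        "talus_centroid": centroid,
    })


def technique_B2(calcaneus: TriMesh, middle_facet_center: np.ndarray | None,
                 tibia_axis: np.ndarray, frame: FootFrame) -> HaaResult:
    """As B1 with the talar middle-facet centre (subtalar joint centre)
    replacing the talus centroid."""
    if middle_facet_center is None:
        raise LandmarkRequiredError(
            "technique B2 requires the landmark 'talus_middle_facet_center'")
    plantar = extreme_point(calcaneus, -frame.dorsal)
    facet = np.asarray(middle_facet_center, dtype=np.float64)
    hind_2d = project_frontal(facet - plantar, frame)
    return _result("B2", hind_2d, tibia_axis, frame, {
        "calcaneus_plantar_point": plantar,
        "middle_facet_center": facet,
    })


# ---------------------------------------------------------------------------
# technique C

def _extreme_2d(pts2d: np.ndarray, direction: np.ndarray,
                tie_tol: float = EXTREME_TIE_TOL) -> np.ndarray:
    proj = pts2d @ direction
    tied = proj >= proj.max() - tie_tol
    return pts2d[tied].mean(axis=0)


def frontal_silhouette_contours(
        calcaneus: TriMesh, frame: FootFrame, max_edge: float = 1.0,
        samples: SurfaceSamples | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Medial and lateral contour segments of the frontal silhouette.

    All surface samples are projected to (medial, dorsal) coordinates; the
    silhouette is split at the mid-height of its dorsal extent and the most
    medial / most lateral points of each half are joined into the medial
    and lateral segments (each returned as (bottom point, top point)).
    """
    samples = _calc_samples(calcaneus, max_edge, samples)
    rel = samples.points - frame.origin
    pts = np.stack([rel @ frame.medial, rel @ frame.dorsal], axis=1)
    mid = 0.5 * (pts[:, 1].min() + pts[:, 1].max())
    bottom = pts[pts[:, 1] <= mid]
    top = pts[pts[:, 1] > mid]
    if len(bottom) == 0 or len(top) == 0:
        raise ContourError("silhouette half is empty")
    med_dir = np.array([1.0, 0.0])
    medial_seg = (_extreme_2d(bottom, med_dir), _extreme_2d(top, med_dir))
    lateral_seg = (_extreme_2d(bottom, -med_dir), _extreme_2d(top, -med_dir))
    return medial_seg, lateral_seg


def _segment_direction(segment: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    d = segment[1] - segment[0]
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ContourError("degenerate contour segment (coincident endpoints)")
    d = d / norm
    if d[1] < 0:
        d = -d
    return d


def technique_C(calcaneus: TriMesh, tibia_axis: np.ndarray, frame: FootFrame,
                max_edge: float = 1.0,
                samples: SurfaceSamples | None = None) -> HaaResult:
    """Bisector of the medial and lateral silhouette contour segments."""
    medial_seg, lateral_seg = frontal_silhouette_contours(
        calcaneus, frame, max_edge, samples)
    d_med = _segment_direction(medial_seg)
    d_lat = _segment_direction(lateral_seg)
    bisector = d_med + d_lat
    bisector = bisector / np.linalg.norm(bisector)
    return _result("C", bisector, tibia_axis, frame, {
        "medial_segment": np.stack(medial_seg),
        "lateral_segment": np.stack(lateral_seg),
        "medial_direction": d_med,
        "lateral_direction": d_lat,
    })


# ---------------------------------------------------------------------------
# techniques D / E

def posterior_box(calcaneus: TriMesh, frame: FootFrame,
                  fraction: float | None = None,
                  max_edge: float = 1.0,
                  samples: SurfaceSamples | None = None) -> PosteriorBox:
    """Clipping box over the posterior part of the calcaneus.

    The box axis is the longitudinal principal axis of the whole calcaneus
    (anterior-positive); its posterior side sits at the most posterior
    surface sample.  With ``fraction`` given, the width is that fraction of
    the total length along the axis; with ``fraction=None`` (plantar-bounded
    mode) the box grows anteriorly until the most plantar point of the bone
    is encapsulated, clamped below at 2 % of the length.
    """
    samples = _calc_samples(calcaneus, max_edge, samples)
    pf = pca_frame(samples, frame)
    axis = pf.axis("longitudinal")
    s = samples.points @ axis
    posterior_limit = float(s.min())
    length = float(s.max() - posterior_limit)
    if length <= 0:
        raise TechniqueError("calcaneus has zero extent along its long axis")

    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise TechniqueError(f"fraction must be in (0, 1], got {fraction}")
        width = fraction * length
        frac = fraction
    else:
        plantar = extreme_point(calcaneus, -frame.dorsal)
        width = float(plantar @ axis) - posterior_limit
        min_width = MIN_E_WIDTH_FRACTION * length
        if width < min_width:
            logger.warning(
                "plantar-bounded box width %.2f mm is below %.0f%% of the "
                "calcaneal length; clamped to %.2f mm",
                width, 100 * MIN_E_WIDTH_FRACTION, min_width)
            width = min_width
        frac = width / length
    return PosteriorBox(axis, posterior_limit, width, frac)


def _slab_vertical_axis(samples: SurfaceSamples, box: PosteriorBox,
                        reference_vertical: np.ndarray,
                        frame: FootFrame) -> tuple[np.ndarray, int]:
    s = samples.points @ box.axis
    keep = s <= box.posterior_limit + box.width
    pts = samples.points[keep]
    w = samples.weights[keep]
    if len(pts) < 4:
        raise SlabRankError(
            f"posterior slab retains only {len(pts)} samples")
    _, axes, variances = weighted_pca(pts, w)
    if variances[2] < 1e-9 * max(variances[0], 1.0):
        raise SlabRankError("posterior slab samples are coplanar")
    # a thin slab's variance ordering differs from the whole bone; take the
    # principal axis best aligned with the whole-calcaneus vertical axis
    cos = axes @ reference_vertical
    k = int(np.argmax(np.abs(cos)))
    axis = axes[k] if cos[k] >= 0 else -axes[k]
    if axis @ frame.dorsal < 0:
        axis = -axis
    return axis, int(len(pts))


def technique_D(calcaneus: TriMesh, tibia_axis: np.ndarray, frame: FootFrame,
                fraction: float = 0.20, max_edge: float = 1.0,
                samples: SurfaceSamples | None = None) -> HaaResult:
    """PCA vertical axis of the posterior ``fraction`` calcaneal slab."""
    samples = _calc_samples(calcaneus, max_edge, samples)
    box = posterior_box(calcaneus, frame, fraction, max_edge, samples)
    pf = pca_frame(samples, frame)
    axis, n_kept = _slab_vertical_axis(samples, box, pf.axis("vertical"), frame)
    hind_2d = project_frontal(axis, frame)
    name = f"D{int(round(100 * fraction))}"
    return _result(name, hind_2d, tibia_axis, frame, {
        "slab_vertical_axis": axis,
        "box_axis": box.axis,
        "box_posterior_limit": box.posterior_limit,
        "box_width": box.width,
        "box_fraction": box.fraction,
        "n_samples_kept": n_kept,
    })


def technique_E(calcaneus: TriMesh, tibia_axis: np.ndarray, frame: FootFrame,
                max_edge: float = 1.0,
                samples: SurfaceSamples | None = None) -> HaaResult:
    """As D, with the plantar-bounded posterior box."""
    samples = _calc_samples(calcaneus, max_edge, samples)
    box = posterior_box(calcaneus, frame, None, max_edge, samples)
    pf = pca_frame(samples, frame)
    axis, n_kept = _slab_vertical_axis(samples, box, pf.axis("vertical"), frame)
    hind_2d = project_frontal(axis, frame)
    return _result("E", hind_2d, tibia_axis, frame, {
        "slab_vertical_axis": axis,
        "box_axis": box.axis,
        "box_posterior_limit": box.posterior_limit,
        "box_width": box.width,
        "box_fraction": box.fraction,
        "n_samples_kept": n_kept,
    })


# ---------------------------------------------------------------------------
# sweep

def compute_all(bones: dict[str, TriMesh],
                landmarks: dict[str, np.ndarray] | None,
                frame: FootFrame,
                max_edge: float = 1.0) -> list[HaaResult]:
    """Run every applicable technique in the fixed order
    A, B1, B2, C, D10, D15, D20, E.

    ``bones`` must contain ``tibia`` and ``calcaneus``; ``talus`` is needed
    for B1 and the ``talus_middle_facet_center`` landmark for B2 -- when
    missing, those techniques are skipped with a warning.
    """
    landmarks = landmarks or {}
    for required in ("tibia", "calcaneus"):
        if required not in bones:
            raise TechniqueError(f"required bone mesh missing: {required}")

    calcaneus = bones["calcaneus"]
    calc_samples = surface_quadrature(calcaneus, max_edge)
    tibia_axis = tibia_vertical_axis(bones["tibia"], frame, max_edge)

    results: list[HaaResult] = []
    results.append(technique_A(calcaneus, tibia_axis, frame,
                               max_edge, calc_samples))
    if "talus" in bones:
        results.append(technique_B1(calcaneus, bones["talus"], tibia_axis, frame))
    else:
        logger.warning("talus mesh missing: technique B1 skipped")
    facet = landmarks.get("talus_middle_facet_center")
    if facet is not None:
        results.append(technique_B2(calcaneus, facet, tibia_axis, frame))
    else:
        logger.warning("landmark 'talus_middle_facet_center' missing: "
                       "technique B2 skipped")
    results.append(technique_C(calcaneus, tibia_axis, frame,
                               max_edge, calc_samples))
    for fraction in (0.10, 0.15, 0.20):
        results.append(technique_D(calcaneus, tibia_axis, frame, fraction,
                                   max_edge, calc_samples))
    results.append(technique_E(calcaneus, tibia_axis, frame,
                               max_edge, calc_samples))
    return results
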
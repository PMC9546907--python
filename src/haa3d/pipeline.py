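"""Library face of the ``measure`` command: bones + landmarks in, foot
frame and per-technique results out."""

from __future__ import annotations

import logging

import numpy as np

from .anatomical_frames import (DEFAULT_GROUND, FootFrame, HaaResult, Plane,
                                build_foot_frame, fit_ground_plane)
from .haa_techniques import LandmarkRequiredError, compute_all
from .mesh_core import LANDMARK_SECOND_MET, TriMesh, extreme_point

logger = logging.getLogger(__name__)


def measure_foot(bones: dict[str, TriMesh],
                 landmarks: dict[str, np.ndarray] | None = None,
                 side: str = "right",
                 max_edge: float = 1.0) -> tuple[FootFrame, list[HaaResult]]:
    """Measure every applicable technique for one foot.

    ``bones`` maps bone names to meshes (``tibia`` and ``calcaneus``
    required; ``talus``, ``metatarsal2`` and ``ground`` optional).  The
    ground plane is fitted to the ground mesh when present, otherwise
    z = 0 is assumed.  The second metatarsal head is taken from the
    metatarsal mesh when present, else from the landmark file.
    """
    landmarks = landmarks or {}
    if "ground" in bones:
        bone_center = np.mean([b.vertices.mean(axis=0)
                               for n, b in bones.items() if n != "ground"],
                              axis=0)
        plane = fit_ground_plane(bones["ground"], toward=bone_center)
    else:
        plane = DEFAULT_GROUND

    plantar = extreme_point(bones["calcaneus"], -plane.normal)
    if "metatarsal2" in bones:
        met_head = extreme_point(bones["metatarsal2"], -plane.normal)
    elif LANDMARK_SECOND_MET in landmarks:
        met_head = landmarks[LANDMARK_SECOND_MET]
    else:
        raise LandmarkRequiredError(
            "need either a metatarsal mesh or the landmark "
            f"'{LANDMARK_SECOND_MET}'")

    frame = build_foot_frame(plantar, met_head, plane, side)
    results = compute_all(bones, landmarks, frame, max_edge)
    return frame, results


def measure_phantom(pset, max_edge: float = 1.0) -> dict[str, float]:
    """Angles per technique for a generated phantom set."""
    _, results = measure_foot(pset.meshes, pset.landmarks,
                              side=pset.spec.side, max_edge=max_edge)
    return {r.technique: r.angle_deg for r in results}
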
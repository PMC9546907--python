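import json

import numpy as np
import pytest

from haa3d.anatomical_frames import pca_frame, tibia_vertical_axis
from haa3d.haa_techniques import (TECHNIQUE_ORDER, LandmarkRequiredError,
                                  compute_all, frontal_silhouette_contours,
                                  posterior_box, technique_A, technique_B1,
                                  technique_B2, technique_C, technique_D,
                                  technique_E)
from haa3d.mesh_core import (RigidTransform, TriMesh, apply_transform,
                             extreme_point, surface_quadrature)
from haa3d.phantom import (PhantomSpec, _tube_mesh, _uv_sphere,
                           generate_phantom)
from haa3d.pipeline import measure_foot, measure_phantom

from conftest import identity_frame, make_box

VERT = np.array([0.0, 1.0])


def seg_angle(seg):
    d = seg[1] - seg[0]
    return np.degrees(np.arctan2(d[0], d[1]))


def prism(profile_yz, length=60.0, step=1.2) -> TriMesh:
    """Prism along x with the given closed CCW (y, z) profile polygon."""
    pts = []
    prof = np.asarray(profile_yz, dtype=np.float64)
    for i in range(len(prof)):
        p0, p1 = prof[i], prof[(i + 1) % len(prof)]
        n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / step)))
        t = np.arange(n) / n
        pts.append(p0 + np.outer(t, p1 - p0))
    profile = np.concatenate(pts)
    stations = np.linspace(0.0, length, int(length / step) + 1)
    return _tube_mesh(stations, np.ones(len(stations)), profile, "calcaneus")


# ---------------------------------------------------------------------------
# technique A

def test_A_upright_phantom_is_zero(upright_angles):
    assert abs(upright_angles["A"]) < 0.5


def test_A_rotation_equivariance(upright_phantom):
    frame = identity_frame()
    calc = upright_phantom.meshes["calcaneus"]
    rot = RigidTransform.about_axis([-1.0, 0, 0], 12.0,
                                    center=frame.origin)
    r0 = technique_A(calc, np.array([0.0, 0, 1]), frame)
    r1 = technique_A(apply_transform(calc, rot), np.array([0.0, 0, 1]), frame)
    assert r1.angle_deg - r0.angle_deg == pytest.approx(12.0, abs=0.5)


def test_A_matches_bruteforce_pca_oracle():
    pset = generate_phantom(PhantomSpec(body_valgus_deg=15.0))
    calc = pset.meshes["calcaneus"]
    frame = identity_frame()
    got = technique_A(calc, np.array([0.0, 0, 1]), frame)

    # oracle: unweighted eigendecomposition of dense uniform random surface
    # points (area-weighted triangle sampling)
    rng = np.random.default_rng(0)
    tri = calc.triangles()
    areas = calc.face_areas()
    idx = rng.choice(len(tri), size=400_000, p=areas / areas.sum())
    u, v = rng.uniform(size=(2, len(idx)))
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    pts = (tri[idx, 0] + u[:, None] * (tri[idx, 1] - tri[idx, 0])
           + v[:, None] * (tri[idx, 2] - tri[idx, 0]))
    d = pts - pts.mean(axis=0)
    vals, vecs = np.linalg.eigh(d.T @ d / len(d))
    vertical = vecs[:, np.argsort(vals)[::-1][1]]
    if vertical[2] < 0:
        vertical = -vertical
    oracle_angle = np.degrees(np.arctan2(vertical[1], vertical[2]))
    assert got.angle_deg == pytest.approx(oracle_angle, abs=0.2)
    assert got.angle_deg == pytest.approx(15.0, abs=0.5)


# ---------------------------------------------------------------------------
# techniques B1/B2

def b_scene(talus_offset):
    calc = make_box((40, 25, 30), center=(0, 0, 15), n=2)
    plantar = np.array([0.0, 0, 0])  # tie centroid of the bottom face
    talus = _uv_sphere(plantar + np.array([0.0, talus_offset[0],
                                           talus_offset[1]]),
                       np.array([12.0, 9.0, 8.0]), 20, 40, "talus")
    return calc, talus


def test_B1_centroid_above_plantar_is_zero():
    calc, talus = b_scene((0.0, 50.0))
    r = technique_B1(calc, talus, np.array([0.0, 0, 1]), identity_frame())
    assert r.angle_deg == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("medial,expected", [(10.0, 11.3099), (-10.0, -11.3099)])
def test_B1_offset_closed_form(medial, expected):
    calc, talus = b_scene((medial, 50.0))
    r = technique_B1(calc, talus, np.array([0.0, 0, 1]), identity_frame())
    assert r.angle_deg == pytest.approx(expected, abs=1e-3)


def test_B2_landmark_closed_form():
    calc, _ = b_scene((0, 50.0))
    r = technique_B2(calc, np.array([0.0, 15.0, 45.0]),
                     np.array([0.0, 0, 1]), identity_frame())
    assert r.angle_deg == pytest.approx(np.degrees(np.arctan2(15, 45)),
                                        abs=1e-6)


def test_B2_minus_B1_trigonometry(decomposed_phantom):
    # oracle: direct trigonometry on the construction offsets
    truth = decomposed_phantom.truth
    angles = measure_phantom(decomposed_phantom)
    expected = (np.degrees(np.arctan2(15, 45)) - np.degrees(np.arctan2(10, 50)))
    assert angles["B2"] - angles["B1"] == pytest.approx(expected, abs=0.05)
    assert truth["B2"] - truth["B1"] == pytest.approx(expected, abs=1e-9)


def test_B2_missing_landmark_raises():
    calc, _ = b_scene((0, 50.0))
    with pytest.raises(LandmarkRequiredError, match="talus_middle_facet_center"):
        technique_B2(calc, None, np.array([0.0, 0, 1]), identity_frame())


# ---------------------------------------------------------------------------
# silhouette contours / technique C

def test_contours_rectangle():
    box = make_box((60, 30, 45), center=(0, 0, 22.5), n=2)
    med, lat = frontal_silhouette_contours(box, identity_frame())
    assert seg_angle(med) == pytest.approx(0.0, abs=1e-6)
    assert seg_angle(lat) == pytest.approx(0.0, abs=1e-6)
    assert med[0][0] == pytest.approx(15.0, abs=1e-6)
    assert lat[0][0] == pytest.approx(-15.0, abs=1e-6)


def test_contours_sheared_rectangle():
    box = make_box((60, 30, 45), n=3)
    v = box.vertices.copy()
    v[:, 1] += v[:, 2] * np.tan(np.radians(10))  # shear: edges tilt 10 deg
    sheared = TriMesh(v, box.faces, "calcaneus")
    med, lat = frontal_silhouette_contours(sheared, identity_frame())
    assert seg_angle(med) == pytest.approx(10.0, abs=1e-6)
    assert seg_angle(lat) == pytest.approx(10.0, abs=1e-6)


def trapezoid_prism(tilt_med_deg, tilt_lat_deg, w=15.0, h=22.5):
    tm = np.tan(np.radians(tilt_med_deg)) * 2 * h
    tl = np.tan(np.radians(tilt_lat_deg)) * 2 * h
    profile = [(w, -h), (w + tm, h), (-w + tl, h), (-w, -h)]
    return prism(profile)


def test_contours_trapezoid_matches_vertex_scan():
    mesh = trapezoid_prism(20.0, 0.0)
    frame = identity_frame()
    med, lat = frontal_silhouette_contours(mesh, frame)
    assert seg_angle(med) == pytest.approx(20.0, abs=0.5)
    assert seg_angle(lat) == pytest.approx(0.0, abs=0.5)

    # oracle: direct min/max scan over projected mesh vertices
    pts = np.stack([mesh.vertices @ frame.medial,
                    mesh.vertices @ frame.dorsal], axis=1)
    mid = 0.5 * (pts[:, 1].min() + pts[:, 1].max())
    bot, top = pts[pts[:, 1] <= mid], pts[pts[:, 1] > mid]
    med_oracle = np.degrees(np.arctan2(
        top[np.argmax(top[:, 0]), 0] - bot[np.argmax(bot[:, 0]), 0],
        top[np.argmax(top[:, 0]), 1] - bot[np.argmax(bot[:, 0]), 1]))
    assert seg_angle(med) == pytest.approx(med_oracle, abs=0.5)


def test_C_symmetric_trapezoid_is_zero():
    mesh = trapezoid_prism(15.0, -15.0)
    r = technique_C(mesh, np.array([0.0, 0, 1]), identity_frame())
    assert r.angle_deg == pytest.approx(0.0, abs=1e-6)


def test_C_parallel_tilt():
    box = make_box((60, 30, 45), n=3)
    v = box.vertices.copy()
    v[:, 1] += v[:, 2] * np.tan(np.radians(10))
    sheared = TriMesh(v, box.faces, "calcaneus")
    r = technique_C(sheared, np.array([0.0, 0, 1]), identity_frame())
    assert r.angle_deg == pytest.approx(10.0, abs=1e-6)


def test_C_bisector_of_unequal_tilts():
    mesh = trapezoid_prism(20.0, 0.0)
    r = technique_C(mesh, np.array([0.0, 0, 1]), identity_frame())
    assert r.angle_deg == pytest.approx(10.0, abs=0.5)


# ---------------------------------------------------------------------------
# posterior boxes / techniques D and E

def test_posterior_box_fraction_width():
    box = make_box((80, 30, 45), n=2, name="calcaneus")
    frame = identity_frame()
    pb = posterior_box(box, frame, fraction=0.10)
    assert pb.width == pytest.approx(8.0, abs=1e-3)
    assert abs(pb.axis @ np.array([1.0, 0, 0])) > 0.999999
    assert pb.fraction == pytest.approx(0.10)


def test_posterior_box_plantar_bounded_width():
    # plantar apex placed 25 mm (31.25 % of 80) anterior of the back tip
    pset = generate_phantom(PhantomSpec(tuberosity_fraction=0.34,
                                        apex_fraction=0.3125))
    calc = pset.meshes["calcaneus"]
    frame = identity_frame()
    pb = posterior_box(calc, frame, fraction=None)
    assert pb.width == pytest.approx(25.0, abs=1.0)


def test_posterior_box_full_fraction_keeps_everything():
    box = make_box((80, 30, 45), n=2, name="calcaneus")
    frame = identity_frame()
    s = surface_quadrature(box, 2.0)
    pb = posterior_box(box, frame, fraction=1.0, samples=s)
    kept = (s.points @ pb.axis) <= pb.posterior_limit + pb.width
    assert kept.all()


def test_posterior_box_nesting_monotone(tilted_phantom):
    calc = tilted_phantom.meshes["calcaneus"]
    frame = identity_frame()
    s = surface_quadrature(calc, 1.0)
    kept = {}
    for f in (0.10, 0.15, 0.20):
        pb = posterior_box(calc, frame, f, samples=s)
        kept[f] = (s.points @ pb.axis) <= pb.posterior_limit + pb.width
    assert np.all(kept[0.10] <= kept[0.15])
    assert np.all(kept[0.15] <= kept[0.20])


def test_D_kept_sample_count_matches_bruteforce(tilted_phantom):
    calc = tilted_phantom.meshes["calcaneus"]
    frame = identity_frame()
    s = surface_quadrature(calc, 1.0)
    pb = posterior_box(calc, frame, 0.10, samples=s)
    expected = int(np.count_nonzero(
        s.points @ pb.axis <= pb.posterior_limit + pb.width))
    r = technique_D(calc, np.array([0.0, 0, 1]), frame, 0.10, samples=s)
    assert r.provenance["n_samples_kept"] == expected


def test_D_separates_tuberosity_from_body(decomposed_phantom):
    # body 10 deg + tuberosity 5 deg: A reads the body, D20 the full tilt
    angles = measure_phantom(decomposed_phantom)
    assert angles["A"] == pytest.approx(10.0, abs=1.0)
    for tech in ("D10", "D15", "D20"):
        assert angles[tech] == pytest.approx(15.0, abs=1.0)


def test_D_tilted_tuberosity_matches_clipped_oracle():
    pset = generate_phantom(PhantomSpec(tuberosity_valgus_deg=15.0))
    calc = pset.meshes["calcaneus"]
    frame = identity_frame()
    s = surface_quadrature(calc, 1.0)
    r = technique_D(calc, np.array([0.0, 0, 1]), frame, 0.15, samples=s)
    assert r.angle_deg == pytest.approx(15.0, abs=1.0)

    # oracle: eigendecomposition of densely random-sampled clipped surface
    rng = np.random.default_rng(1)
    tri = calc.triangles()
    areas = calc.face_areas()
    idx = rng.choice(len(tri), size=1_200_000, p=areas / areas.sum())
    u, v = rng.uniform(size=(2, len(idx)))
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    pts = (tri[idx, 0] + u[:, None] * (tri[idx, 1] - tri[idx, 0])
           + v[:, None] * (tri[idx, 2] - tri[idx, 0]))
    pb = posterior_box(calc, frame, 0.15, samples=s)
    kept = pts[(pts @ pb.axis) <= pb.posterior_limit + pb.width]
    d = kept - kept.mean(axis=0)
    vals, vecs = np.linalg.eigh(d.T @ d / len(d))
    ref = pca_frame(s, frame).axis("vertical")
    cos = vecs.T @ ref
    vertical = vecs[:, np.argmax(np.abs(cos))]
    if vertical[2] < 0:
        vertical = -vertical
    oracle = np.degrees(np.arctan2(vertical[1], vertical[2]))
    assert r.angle_deg == pytest.approx(oracle, abs=0.4)


def test_E_equals_D20_when_boxes_match():
    # apex placed at 19.9 % of the length: E's plantar-bounded box and the
    # 20 % box clip (essentially) the same slab
    pset = generate_phantom(PhantomSpec(body_valgus_deg=8.0,
                                        apex_fraction=0.199))
    angles = measure_phantom(pset)
    assert angles["E"] == pytest.approx(angles["D20"], abs=0.1)


def test_E_upright_zero(upright_angles):
    assert abs(upright_angles["E"]) < 0.5


def test_E_tilted_tuberosity(upright_phantom):
    pset = generate_phantom(PhantomSpec(tuberosity_valgus_deg=15.0))
    angles = measure_phantom(pset)
    assert angles["E"] == pytest.approx(15.0, abs=1.0)


# ---------------------------------------------------------------------------
# compute_all

def test_compute_all_full_phantom(upright_phantom):
    frame, results = measure_foot(upright_phantom.meshes,
                                  upright_phantom.landmarks)
    assert [r.technique for r in results] == list(TECHNIQUE_ORDER)


def test_compute_all_skips_missing_inputs(upright_phantom, caplog):
    bones = {k: v for k, v in upright_phantom.meshes.items() if k != "talus"}
    with caplog.at_level("WARNING"):
        frame, results = measure_foot(bones, landmarks={
            "second_met_head_plantar":
                upright_phantom.landmarks["second_met_head_plantar"]})
    assert [r.technique for r in results] == ["A", "C", "D10", "D15",
                                              "D20", "E"]
    joined = " ".join(r.message for r in caplog.records)
    assert "B1 skipped" in joined and "B2 skipped" in joined


def test_compute_all_missing_calcaneus_fatal(upright_phantom):
    bones = {"tibia": upright_phantom.meshes["tibia"]}
    with pytest.raises(Exception, match="calcaneus"):
        compute_all(bones, {}, identity_frame())


def test_compute_all_deterministic(upright_phantom):
    def run():
        _, results = measure_foot(upright_phantom.meshes,
                                  upright_phantom.landmarks)
        return json.dumps([r.to_dict() for r in results], sort_keys=True)

    assert run() == run()


def test_calcaneus_only_rotation_shifts_ACDE(upright_phantom):
    frame, base = measure_foot(upright_phantom.meshes,
                               upright_phantom.landmarks)
    base = {r.technique: r.angle_deg for r in base}
    calc = upright_phantom.meshes["calcaneus"]
    centroid = calc.vertices.mean(axis=0)
    delta = 8.0
    rot = RigidTransform.about_axis([-1.0, 0, 0], delta, center=centroid)
    meshes = dict(upright_phantom.meshes)
    meshes["calcaneus"] = apply_transform(calc, rot)
    _, rotated = measure_foot(meshes, upright_phantom.landmarks)
    rotated = {r.technique: r.angle_deg for r in rotated}
    for tech in ("A", "C", "D10", "D15", "D20", "E"):
        assert rotated[tech] - base[tech] == pytest.approx(delta, abs=0.5)
    # B endpoints move with the bone, so only the direction is asserted
    b_shifts = [rotated[t] - base[t] for t in ("B1", "B2")]
    assert np.sign(b_shifts[0]) == np.sign(b_shifts[1])
    assert all(abs(s) < delta for s in b_shifts)
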
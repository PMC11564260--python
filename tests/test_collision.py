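"""Collision kernel: narrow phase, spatial-index equivalence, truncation."""

import numpy as np
import pytest

from ffmkit import (
    DataError,
    HipParams,
    CamBump,
    LabeledMesh,
    RegionLabel,
    build_hip_frame,
    generate_hip,
    meshes_collide,
    predicted_cam_contact_angle,
    tri_tri_intersect,
    truncate_at_impingement,
)
from ffmkit.kinematics import Branch, MotionProtocol, protocol_poses
from ffmkit.synthetic_hip import _polar_grid


def blob(rng, center, radius=1.0, bumpy=0.0, label=RegionLabel.OTHER):
    angles = np.linspace(0, 175, 8)
    v, f, _ = _polar_grid(np.array([0.0, 1.0, 0.0]), radius, angles, 10)
    if bumpy:
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        v = v * (1 + bumpy * rng.uniform(-1, 1, len(v)))[:, None]
    return LabeledMesh(v + center, f, np.full(len(f), int(label), dtype=np.int8))


def test_far_spheres_do_not_collide():
    rng = np.random.default_rng(0)
    a = blob(rng, [0, 0, 0])
    b = blob(rng, [3, 0, 0])
    assert not meshes_collide(a, b).collided


def test_overlapping_spheres_collide():
    rng = np.random.default_rng(0)
    a = blob(rng, [0, 0, 0])
    b = blob(rng, [1.5, 0, 0])
    rep = meshes_collide(a, b)
    assert rep.collided
    assert rep.face_pair is not None


def test_empty_mesh_error():
    rng = np.random.default_rng(0)
    a = blob(rng, [0, 0, 0])
    empty = LabeledMesh(np.zeros((0, 3)), np.zeros((0, 3), int), np.zeros(0, np.int8))
    with pytest.raises(DataError):
        meshes_collide(a, empty)


def test_collision_symmetric():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = blob(rng, rng.uniform(-1, 1, 3), bumpy=0.2)
        b = blob(rng, rng.uniform(-1, 1, 3), bumpy=0.2)
        assert meshes_collide(a, b).collided == meshes_collide(b, a).collided


def test_tolerance_turns_proximity_into_contact():
    rng = np.random.default_rng(2)
    a = blob(rng, [0, 0, 0])
    b = blob(rng, [2.3, 0, 0])  # 0.3 mm gap between unit spheres
    assert not meshes_collide(a, b, tolerance=0.0).collided
    assert meshes_collide(a, b, tolerance=0.5).collided


def test_indexed_equals_exhaustive_random_pairs():
    rng = np.random.default_rng(3)
    mismatches = 0
    n_hit = 0
    for _ in range(25):
        a = blob(rng, rng.uniform(-1.6, 1.6, 3), bumpy=0.3)
        b = blob(rng, rng.uniform(-1.6, 1.6, 3), bumpy=0.3)
        fast = meshes_collide(a, b).collided
        slow = meshes_collide(a, b, exhaustive=True).collided
        n_hit += fast
        mismatches += fast != slow
    assert mismatches == 0
    assert 0 < n_hit < 25  # the sample exercises both outcomes


def test_head_lunate_pairs_excluded():
    """Articular near-contact is not impingement: intersecting triangles
    labeled HEAD/LUNATE are ignored, identical geometry with other labels
    is a collision."""
    tri_a = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], dtype=float)
    tri_b = np.array([[0.5, 0.5, -1], [0.5, 0.5, 1], [1.5, 1.5, 0]], dtype=float)
    head = LabeledMesh(tri_a, [[0, 1, 2]], [int(RegionLabel.HEAD)])
    lunate = LabeledMesh(tri_b, [[0, 1, 2]], [int(RegionLabel.LUNATE)])
    other = LabeledMesh(tri_b, [[0, 1, 2]], [int(RegionLabel.OTHER)])
    assert not meshes_collide(head, lunate).collided
    assert meshes_collide(head, other).collided
    assert meshes_collide(head, lunate, excluded_label_pairs=frozenset()).collided


def _rotation_sweep_setup():
    """Femur blob orbits the origin; pelvis blob parked on its path."""
    rng = np.random.default_rng(4)
    femur = blob(rng, [0, 10, 0])  # 10 mm lever arm
    angle = np.radians(35.0)  # internal rotation carries +y toward -x
    pelvis = blob(rng, [-10 * np.sin(angle), 10 * np.cos(angle), 0])
    br = Branch("rotation", +1, 120.0)
    poses = protocol_poses(MotionProtocol("sweep", "sweep", (br,)))
    return femur, pelvis, poses


def test_truncation_is_prefix_and_matches_per_pose_oracle():
    femur, pelvis, poses = _rotation_sweep_setup()
    kept, rep = truncate_at_impingement(poses, pelvis, femur)
    per_pose = [
        meshes_collide(femur.transformed(p.rotation), pelvis, exhaustive=True).collided
        for p in poses
    ]
    first = per_pose.index(True)
    assert rep.first_colliding_step == first
    assert [p.step_index for p in kept] == list(range(first))
    assert 0 < first < len(poses)


def test_truncation_keeps_all_when_no_collision():
    femur, pelvis, poses = _rotation_sweep_setup()
    far_pelvis = pelvis.transformed(None, [100.0, 0, 0])
    kept, rep = truncate_at_impingement(poses, far_pelvis, femur)
    assert len(kept) == len(poses)
    assert rep.first_colliding_step is None


def test_colliding_neutral_raises():
    rng = np.random.default_rng(5)
    femur = blob(rng, [0, 0, 0])
    pelvis = blob(rng, [1.0, 0, 0])
    br = Branch("rotation", +1, 30.0)
    poses = protocol_poses(MotionProtocol("x", "x", (br,)))
    with pytest.raises(DataError, match="neutral"):
        truncate_at_impingement(poses, pelvis, femur)


def test_cam_hip_collides_at_predicted_abduction_step():
    loc = (0.0, float(np.cos(np.radians(110))), float(np.sin(np.radians(110))))
    params = HipParams(cam_bump=CamBump(amplitude_mm=3.0, extent_deg=12.0, location=loc))
    predicted = predicted_cam_contact_angle(params, motion="abduction", direction=+1)
    assert predicted is not None
    pelvis, femur, _ = generate_hip(params)
    _, pelvis_c, femur_c = build_hip_frame(pelvis, femur)
    br = Branch("abduction", +1, 50.0)
    poses = protocol_poses(MotionProtocol("abd", "abd", (br,)))
    _, rep = truncate_at_impingement(poses, pelvis_c, femur_c)
    assert rep.first_colliding_step is not None
    observed = poses[rep.first_colliding_step].angles[1]
    # first colliding 10-degree step brackets the analytic contact angle
    assert abs(observed - predicted) <= 10.0


def test_tri_tri_coplanar_overlap():
    a = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)
    b = a + np.array([0.2, 0.2, 0.0])
    assert tri_tri_intersect(a, b)[0]
    c = a + np.array([5.0, 0.0, 0.0])
    assert not tri_tri_intersect(a, c)[0]
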
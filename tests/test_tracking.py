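"""Footprints, medial-view projection and tracking-pattern booleans."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from shapely.geometry import Point

from ffmkit import (
    DataError,
    build_hip_frame,
    characterize_fovea,
    fossa_region_2d,
    fovea_footprint,
    pattern_to_svg,
    project_spherical_cap,
    tracking_pattern,
)
from ffmkit.kinematics import Branch, MotionProtocol, protocol_poses
from ffmkit.tracking import Footprint


def _pose(flex=0.0, abd=0.0, rot=0.0):
    from ffmkit.kinematics import Pose, compose_rotation

    return Pose("t", 0, 0, (flex, abd, rot), compose_rotation(flex, abd, rot))


def _disc_footprint(center_xy, radius_mm, R=2000.0):
    """Footprint whose projection is (nearly) a planar disc: small cap close
    to the view axis on a huge sphere."""
    cx, cz = center_xy
    d = np.array([cx / R, 0.0, cz / R])
    d = np.array([d[0], np.sqrt(1 - d[0] ** 2 - d[2] ** 2), d[2]])
    alpha = np.degrees(np.arcsin(radius_mm / R))
    poly = project_spherical_cap(d, alpha, R, n_segments=360)
    return Footprint(_pose(), d, alpha, R, poly)


def test_footprint_center_tracks_pose(framed_offset_hip):
    frame, pelvis_c, femur_c, truth = framed_offset_hip
    center, radius = characterize_fovea(femur_c, frame)
    np.testing.assert_allclose(center, truth.fovea_direction, atol=1e-6)
    assert radius == pytest.approx(truth.fovea_angular_radius, abs=0.05)

    fp0 = fovea_footprint(femur_c, _pose(), frame, (center, radius))
    np.testing.assert_allclose(fp0.center_dir, center, atol=1e-12)

    pose = _pose(rot=-30.0)  # 30 deg external rotation
    fp = fovea_footprint(femur_c, pose, frame, (center, radius))
    oracle = Rotation.from_euler("YXZ", [0, 0, -30], degrees=True).as_matrix() @ center
    np.testing.assert_allclose(fp.center_dir, oracle, atol=1e-12)


def test_footprint_spherical_area_pose_invariant(framed_offset_hip):
    frame, _, femur_c, _ = framed_offset_hip
    fov = characterize_fovea(femur_c, frame)
    areas = {
        fovea_footprint(femur_c, _pose(*ang), frame, fov).spherical_area()
        for ang in [(0, 0, 0), (90, 0, 0), (30, -20, 40), (0, 50, 0)]
    }
    assert max(areas) - min(areas) < 1e-9


def test_fossa_projection_matches_closed_form(framed_offset_hip):
    frame, pelvis_c, _, truth = framed_offset_hip
    poly = fossa_region_2d(pelvis_c, frame)
    expected = np.pi * (truth.acetabular_radius * np.sin(np.radians(truth.fossa_angular_radius))) ** 2
    assert poly.area == pytest.approx(expected, rel=0.02)


def test_off_axis_cap_foreshortened():
    on_axis = project_spherical_cap([0, 1, 0], 20.0, 24.0)
    off_axis = project_spherical_cap([0, np.cos(0.6), np.sin(0.6)], 20.0, 24.0)
    assert off_axis.area < on_axis.area


def test_far_hemisphere_cap_invisible():
    assert project_spherical_cap([0, -1, 0], 20.0, 24.0) is None


def test_fossa_outline_invariant_to_rigid_pretransform(offset_hip):
    pelvis, femur, _ = offset_hip
    frame0, pelvis_0, _ = build_hip_frame(pelvis, femur)
    base = fossa_region_2d(pelvis_0, frame0)
    R = Rotation.from_rotvec([1.0, 0.3, -0.5]).as_matrix()
    frame1, pelvis_1, _ = build_hip_frame(
        pelvis.transformed(R, [4.0, 5.0, -6.0]), femur.transformed(R, [4.0, 5.0, -6.0])
    )
    moved = fossa_region_2d(pelvis_1, frame1)
    assert moved.symmetric_difference(base).area < 1e-3 * base.area


def test_union_of_disjoint_discs():
    r = 3.0
    fps = [_disc_footprint((-10, 0), r), _disc_footprint((10, 0), r)]
    fossa = Point(0, 0).buffer(1.0)
    pat = tracking_pattern(fps, fossa, protocol="t")
    assert pat.area_total == pytest.approx(2 * np.pi * r**2, rel=0.005)


def test_union_of_identical_discs_not_double_counted():
    r = 3.0
    fps = [_disc_footprint((0, 5), r), _disc_footprint((0, 5), r)]
    fossa = Point(0, 0).buffer(1.0)
    pat = tracking_pattern(fps, fossa, protocol="t")
    assert pat.area_total == pytest.approx(np.pi * r**2, rel=0.005)


def test_overlapping_discs_match_lens_formula():
    r, d = 3.0, 4.0
    fps = [_disc_footprint((0, 0), r), _disc_footprint((d, 0), r)]
    fossa = Point(50, 50).buffer(1.0)
    pat = tracking_pattern(fps, fossa, protocol="t")
    lens = 2 * r**2 * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r**2 - d**2)
    expected = 2 * np.pi * r**2 - lens
    assert pat.area_total == pytest.approx(expected, rel=0.005)


def test_partition_conservation_polygon_backend(framed_offset_hip, rom):
    frame, pelvis_c, femur_c, _ = framed_offset_hip
    fossa2d = fossa_region_2d(pelvis_c, frame)
    fov = characterize_fovea(femur_c, frame)
    br = Branch("rotation", -1, 40.0)
    poses = protocol_poses(MotionProtocol("er", "er", (br,)))
    fps = [fovea_footprint(femur_c, p, frame, fov) for p in poses]
    pat = tracking_pattern(fps, fossa2d, protocol="er")
    assert pat.area_inside + pat.area_outside == pytest.approx(pat.area_total, rel=1e-6)
    assert min(pat.area_inside, pat.area_outside, pat.area_total) >= 0


def test_union_monotone_in_footprints(framed_offset_hip):
    frame, pelvis_c, femur_c, _ = framed_offset_hip
    fossa2d = fossa_region_2d(pelvis_c, frame)
    fov = characterize_fovea(femur_c, frame)
    br = Branch("rotation", -1, 40.0)
    poses = protocol_poses(MotionProtocol("er", "er", (br,)))
    fps = [fovea_footprint(femur_c, p, frame, fov) for p in poses]
    prev = 0.0
    for k in range(1, len(fps) + 1):
        area = tracking_pattern(fps[:k], fossa2d, protocol="er").area_total
        assert area >= prev - 1e-9
        prev = area


def test_raster_backend_agrees_with_polygon(framed_offset_hip):
    frame, pelvis_c, femur_c, _ = framed_offset_hip
    fossa2d = fossa_region_2d(pelvis_c, frame)
    fov = characterize_fovea(femur_c, frame)
    fps = [fovea_footprint(femur_c, _pose(rot=a), frame, fov) for a in (0, -20, -40)]
    res = 0.1
    poly = tracking_pattern(fps, fossa2d, protocol="t", backend="polygon")
    rast = tracking_pattern(fps, fossa2d, resolution=res, protocol="t", backend="raster")
    bound = 2 * res * poly.union_region.length
    assert abs(poly.area_total - rast.area_total) < bound
    assert abs(poly.area_outside - rast.area_outside) < bound


def test_empty_pattern_is_error():
    fossa = Point(0, 0).buffer(1.0)
    with pytest.raises(DataError):
        tracking_pattern([], fossa, protocol="t")


def test_svg_export(tmp_path, framed_offset_hip):
    frame, pelvis_c, femur_c, _ = framed_offset_hip
    fossa2d = fossa_region_2d(pelvis_c, frame)
    fov = characterize_fovea(femur_c, frame)
    fps = [fovea_footprint(femur_c, _pose(rot=-30.0), frame, fov)]
    pat = tracking_pattern(fps, fossa2d, protocol="demo")
    out = tmp_path / "demo.svg"
    pattern_to_svg(pat, out)
    text = out.read_text()
    assert text.startswith("<svg") and "</svg>" in text
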
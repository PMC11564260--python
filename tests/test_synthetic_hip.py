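"""Generator contracts and the analytic FFM oracle."""

import numpy as np
import pytest
from conftest import cranial_fovea

from ffmkit import (
    CamBump,
    ConfigError,
    HipParams,
    RegionLabel,
    analytic_ffm,
    build_hip_frame,
    extract_region,
    fit_head_sphere,
    fossa_region_2d,
    fovea_footprint,
    generate_hip,
    generate_rating_table,
    icc_agreement,
    protocols_by_name,
)


def test_generator_deterministic(default_params):
    p1, f1, _ = generate_hip(default_params)
    p2, f2, _ = generate_hip(default_params)
    np.testing.assert_array_equal(p1.vertices, p2.vertices)
    np.testing.assert_array_equal(p1.faces, p2.faces)
    np.testing.assert_array_equal(f1.face_labels, f2.face_labels)


def test_infeasible_fossa_rejected():
    with pytest.raises(ConfigError):
        HipParams(fossa_angular_radius=75.0, lunate_outer_angular_radius=70.0)


def test_head_sphere_recovered(default_hip, default_params):
    _, femur, _ = default_hip
    _, radius, _ = fit_head_sphere(femur)
    assert radius == pytest.approx(default_params.head_radius, rel=0.005)


def test_region_areas_match_cap_formulas(default_hip, default_params):
    pelvis, femur, truth = default_hip
    fossa = extract_region(pelvis, RegionLabel.FOSSA)
    fovea = extract_region(femur, RegionLabel.FOVEA)
    assert fossa.area() == pytest.approx(truth.fossa_cap_area, rel=0.02)
    assert fovea.area() == pytest.approx(truth.fovea_cap_area, rel=0.02)
    # refinement halves the deficit direction: finer mesh is closer
    fine = HipParams(mesh_resolution=default_params.mesh_resolution / 2)
    pel_f, _, truth_f = generate_hip(fine)
    err_coarse = abs(fossa.area() - truth.fossa_cap_area)
    err_fine = abs(extract_region(pel_f, RegionLabel.FOSSA).area() - truth_f.fossa_cap_area)
    assert err_fine < err_coarse


def test_concentric_fovea_inside_fossa_at_neutral(default_hip):
    pelvis, femur, _ = default_hip
    frame, pelvis_c, femur_c = build_hip_frame(pelvis, femur)
    fossa2d = fossa_region_2d(pelvis_c, frame)
    from ffmkit.kinematics import Branch, MotionProtocol, protocol_poses

    neutral = protocol_poses(MotionProtocol("n", "n", (Branch("flexion", 1, 0.0),)))[0]
    fp = fovea_footprint(femur_c, neutral, frame)
    assert fp.polygon.within(fossa2d.buffer(1e-6))


def test_oracle_zero_when_trajectory_stays_inside():
    # concentric fovea (14 deg disc), 10 deg sweep inside a 30 deg fossa cap
    from ffmkit import RomLimits

    p = HipParams()
    prot = protocols_by_name(RomLimits(internal_rotation=10.0))["internal_rotation"]
    assert analytic_ffm(p, prot) == 0.0


def test_oracle_one_when_trajectory_fully_outside(rom):
    p = HipParams(
        fovea_direction=cranial_fovea(60.0),
        fossa_angular_radius=15.0,
        fovea_angular_radius=10.0,
    )
    prot = protocols_by_name(rom)["internal_rotation"]
    assert analytic_ffm(p, prot) == 1.0


def test_oracle_refuses_cam():
    p = HipParams(cam_bump=CamBump(location=(0.0, -0.5, 0.87)))
    with pytest.raises(ConfigError):
        analytic_ffm(p, protocols_by_name()["flexion"])


def test_oracle_grid_convergence(rom):
    """A single ER arc exiting the cap: coarse oracle vs an independent
    fine polar-coordinate integration on the sphere agrees within 1e-3."""
    p = HipParams(fovea_direction=cranial_fovea(20.0), fossa_angular_radius=25.0)
    prot = protocols_by_name(rom)["external_rotation"]
    coarse = analytic_ffm(p, prot, grid=400)

    # independent scheme: lat-lon sampling with projected-area weights y/R
    from ffmkit.kinematics import protocol_poses

    f = np.asarray(p.fovea_direction)
    dirs = np.array([q.rotation @ f for q in protocol_poses(prot)])
    alpha = np.radians(p.fovea_angular_radius)
    theta_f = np.radians(p.fossa_angular_radius)
    th = np.linspace(0, np.pi / 2, 1500)  # polar from +y, near hemisphere only
    ph = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    Q = np.stack(
        [np.sin(TH) * np.cos(PH), np.cos(TH), np.sin(TH) * np.sin(PH)], axis=-1
    )
    w = np.sin(TH) * np.cos(TH)  # dA_proj = (y/R) dA_sphere
    in_union = np.zeros(TH.shape, dtype=bool)
    for d in dirs:
        in_union |= Q @ d >= np.cos(alpha)
    in_fossa = Q[..., 1] >= np.cos(theta_f)
    total = w[in_union].sum()
    outside = w[in_union & ~in_fossa].sum()
    reference = outside / total
    assert coarse == pytest.approx(reference, abs=1e-3)


def test_klaue_monotonicity_cranial_offset(rom):
    """More cranial fovea placement never decreases the external-rotation
    mismatch on ideal geometry."""
    prot = protocols_by_name(rom)["external_rotation"]
    vals = [
        analytic_ffm(HipParams(fovea_direction=cranial_fovea(off)), prot)
        for off in (0, 10, 20, 30, 40)
    ]
    diffs = np.diff(vals)
    assert np.all(diffs >= -2e-3)
    assert vals[-1] > vals[0]


def test_rating_table_degenerate_cases():
    t = generate_rating_table(6, 3, 2, subject_sd=2.0, rater_sd=0.0, error_sd=0.0, seed=0, motions=["m"])
    wide = t.df.pivot_table(index="subject", columns=["rater", "session"], values="value")
    assert np.allclose(wide.to_numpy(), wide.to_numpy()[:, [0]])  # identical per subject

    t0 = generate_rating_table(40, 3, 1, subject_sd=0.0, rater_sd=0.0, error_sd=1.0, seed=3, motions=["m"])
    m = t0.matrix("m", columns="rater", fixed={"session": 0})
    est = icc_agreement(m).estimate
    assert abs(est) < 0.35  # no subject variance -> ICC near zero


def test_rating_table_icc_near_population():
    ests = [
        icc_agreement(
            generate_rating_table(15, 3, 1, 3.0, 0.0, 1.0, seed=s, motions=["m"]).matrix(
                "m", columns="rater", fixed={"session": 0}
            )
        ).estimate
        for s in range(40)
    ]
    assert np.mean(ests) == pytest.approx(0.9, abs=0.03)
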
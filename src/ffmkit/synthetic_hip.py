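"""Parametric synthetic hips with analytic ground truth.

The generator emits a pelvis/femur surface pair with known geometry so every
downstream stage is testable without patient CT models: the femoral head is
a sphere meshed as a polar grid centered on the fovea axis (so the FOVEA
label boundary is an exact vertex ring at the requested angular radius),
and the acetabulum is a spherical shell band at ``head_radius + clearance``
with the FOSSA cap and LUNATE band separated by an exact ring.  Optional
deformities: a Gaussian cam bump at the head-neck junction (amplitude and
extent map only qualitatively to alpha-angle severity) and variable lunate
coverage / fovea placement (dysplasia analogs).

:func:`analytic_ffm` is the independent oracle for the pipeline's
fossa-foveolar mismatch index: on the ideal sphere-on-sphere geometry it
integrates the union of rotated fovea discs directly on the sphere,
partitioned by the fossa cap, using the same medial-view projection
convention (near hemisphere only, orthographic along +y) as the mesh
pipeline — but sharing none of its code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, NumericalError
from .kinematics import MotionProtocol, RomLimits, protocol_poses
from .mesh_model import LabeledMesh, RegionLabel

CANONICAL_CUP_AXIS = (0.0, 1.0, 0.0)  # medial, right-hip convention


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ConfigError("zero-length direction vector")
    return v / n


def _basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


@dataclass(frozen=True)
class CamBump:
    """Smooth radial Gaussian protrusion at the head-neck junction."""

    amplitude_mm: float = 3.0
    extent_deg: float = 12.0  # Gaussian sigma of the angular profile
    location: tuple[float, float, float] = (1.0, -0.5, -0.2)  # anterolateral junction


@dataclass(frozen=True)
class HipParams:
    """Stated world of the synthetic hip (all lengths mm, angles degrees)."""

    head_radius: float = 24.0
    fovea_direction: tuple[float, float, float] = CANONICAL_CUP_AXIS
    fovea_angular_radius: float = 14.0
    acetabular_center_direction: tuple[float, float, float] = CANONICAL_CUP_AXIS
    lunate_outer_angular_radius: float = 70.0
    fossa_angular_radius: float = 30.0
    fossa_center_direction: tuple[float, float, float] = CANONICAL_CUP_AXIS
    cam_bump: CamBump | None = None
    clearance: float = 0.5
    mesh_resolution: float = 1.5  # target edge length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise ConfigError("head_radius must be > 0")
        if self.clearance < 0:
            raise ConfigError("clearance must be >= 0")
        if not (0 < self.fossa_angular_radius < self.lunate_outer_angular_radius < 90):
            raise ConfigError(
                "need 0 < fossa_angular_radius < lunate_outer_angular_radius < 90 "
                f"(got {self.fossa_angular_radius}, {self.lunate_outer_angular_radius})"
            )
        if not (0 < self.fovea_angular_radius < 90):
            raise ConfigError("fovea_angular_radius must be in (0, 90)")
        if self.mesh_resolution <= 0:
            raise ConfigError("mesh_resolution must be > 0")
        if self.cam_bump is not None:
            sep = np.degrees(
                np.arccos(
                    np.clip(_unit(self.cam_bump.location) @ _unit(self.fovea_direction), -1, 1)
                )
            )
            if sep < self.fovea_angular_radius + 2.5 * self.cam_bump.extent_deg:
                raise ConfigError("cam bump overlaps the fovea patch")

    @property
    def acetabular_radius(self) -> float:
        return self.head_radius + self.clearance

    def cap_area_fossa(self) -> float:
        """Closed-form spherical-cap area 2 pi R^2 (1 - cos theta) of the fossa."""
        R = self.acetabular_radius
        return 2 * np.pi * R**2 * (1 - np.cos(np.radians(self.fossa_angular_radius)))

    def cap_area_fovea(self) -> float:
        r = self.head_radius
        return 2 * np.pi * r**2 * (1 - np.cos(np.radians(self.fovea_angular_radius)))


@dataclass
class GroundTruth:
    """Analytic truth consistent with the emitted meshes (within meshing tol)."""

    hip_center: np.ndarray
    head_radius: float
    acetabular_radius: float
    fossa_center_direction: np.ndarray
    fossa_angular_radius: float
    fovea_direction: np.ndarray
    fovea_angular_radius: float
    lunate_outer_angular_radius: float
    transverse_ligament_origin: np.ndarray
    fossa_cap_area: float
    fovea_cap_area: float
    params: HipParams = field(repr=False, default=None)


# -- mesh builders -----------------------------------------------------


def _polar_grid(axis: np.ndarray, radius: float, ring_angles_deg: np.ndarray, n_seg: int):
    """Vertices/faces of a sphere patch built as rings around ``axis``.

    ``ring_angles_deg[0]`` must be 0 (apex).  Returns (vertices, faces,
    face_band): face_band[i] = index of the outer ring bounding face i, so a
    face lies within polar angle ring_angles_deg[face_band[i]].
    """
    u, v = _basis(axis)
    phis = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    verts = [radius * axis]
    for theta in np.radians(ring_angles_deg[1:]):
        ring = radius * (
            np.cos(theta) * axis[None, :]
            + np.sin(theta) * (np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v)
        )
        verts.append(ring)
    vertices = np.vstack([verts[0][None, :], *verts[1:]])
    faces = []
    band = []
    # apex fan to ring 1
    for j in range(n_seg):
        faces.append([0, 1 + j, 1 + (j + 1) % n_seg])
        band.append(1)
    for i in range(1, len(ring_angles_deg) - 1):
        a0 = 1 + (i - 1) * n_seg
        b0 = 1 + i * n_seg
        for j in range(n_seg):
            j1 = (j + 1) % n_seg
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
            band.extend([i + 1, i + 1])
    return vertices, np.asarray(faces, dtype=np.int64), np.asarray(band, dtype=int)


def _ring_angles(stops_deg: list[float], radius: float, resolution: float) -> np.ndarray:
    """Monotone ring angles from 0 through each stop, spaced ~resolution of arc."""
    angles = [0.0]
    for lo, hi in zip([0.0] + stops_deg[:-1], stops_deg):
        span = np.radians(hi - lo) * radius
        n = max(2, int(np.ceil(span / resolution)))
        angles.extend(np.linspace(lo, hi, n + 1)[1:].tolist())
    return np.asarray(angles)


def _generate_pelvis(p: HipParams) -> tuple[LabeledMesh, np.ndarray]:
    axis = _unit(p.acetabular_center_direction)
    fossa_dir = _unit(p.fossa_center_direction)
    R = p.acetabular_radius
    concentric = float(axis @ fossa_dir) > 1 - 1e-12
    if concentric:
        angles = _ring_angles([p.fossa_angular_radius, p.lunate_outer_angular_radius], R, p.mesh_resolution)
    else:
        angles = _ring_angles([p.lunate_outer_angular_radius], R, p.mesh_resolution)
    n_seg = max(12, int(np.ceil(2 * np.pi * R * np.sin(np.radians(p.lunate_outer_angular_radius)) / p.mesh_resolution)))
    verts, faces, band = _polar_grid(axis, R, angles, n_seg)
    if concentric:
        labels = np.where(
            angles[band] <= p.fossa_angular_radius + 1e-9,
            int(RegionLabel.FOSSA),
            int(RegionLabel.LUNATE),
        ).astype(np.int8)
    else:
        cents = verts[faces].mean(axis=1)
        cdir = cents / np.linalg.norm(cents, axis=1, keepdims=True)
        in_fossa = cdir @ fossa_dir >= np.cos(np.radians(p.fossa_angular_radius))
        labels = np.where(in_fossa, int(RegionLabel.FOSSA), int(RegionLabel.LUNATE)).astype(np.int8)

    # transverse-ligament origin: most inferior point of the fossa boundary circle
    u, v = _basis(fossa_dir)
    ts = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
    thf = np.radians(p.fossa_angular_radius)
    circ = R * (
        np.cos(thf) * fossa_dir[None, :]
        + np.sin(thf) * (np.cos(ts)[:, None] * u + np.sin(ts)[:, None] * v)
    )
    tl = circ[int(np.argmin(circ[:, 2]))]
    mesh = LabeledMesh(verts, faces, labels, {"transverse_ligament_origin": tl})
    return mesh, tl


def _generate_femur(p: HipParams) -> LabeledMesh:
    fovea_dir = _unit(p.fovea_direction)
    r = p.head_radius
    angles = _ring_angles([p.fovea_angular_radius, 175.0], r, p.mesh_resolution)
    n_seg = max(12, int(np.ceil(2 * np.pi * r / p.mesh_resolution)))
    verts, faces, band = _polar_grid(fovea_dir, r, angles, n_seg)
    labels = np.where(
        angles[band] <= p.fovea_angular_radius + 1e-9,
        int(RegionLabel.FOVEA),
        int(RegionLabel.HEAD),
    ).astype(np.int8)

    if p.cam_bump is not None:
        loc = _unit(p.cam_bump.location)
        sigma = np.radians(p.cam_bump.extent_deg)
        dirs = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        psi = np.arccos(np.clip(dirs @ loc, -1, 1))
        h = p.cam_bump.amplitude_mm * np.exp(-0.5 * (psi / sigma) ** 2)
        verts = verts * (1 + h / r)[:, None]
        cents = verts[faces].mean(axis=1)
        cdir = cents / np.linalg.norm(cents, axis=1, keepdims=True)
        on_bump = np.arccos(np.clip(cdir @ loc, -1, 1)) <= 2.5 * sigma
        labels = np.where(
            on_bump & (labels != int(RegionLabel.FOVEA)), int(RegionLabel.OTHER), labels
        ).astype(np.int8)

    # short neck/shaft stub: open tube toward lateral-inferior, femur-internal
    # overlap with the head sphere is harmless (only femur-pelvis pairs are
    # collision tested)
    n_axis = _unit((0.0, -0.6, -0.8))
    e1, e2 = _basis(n_axis)
    stub_r = 0.45 * r
    n_stub = 24
    phis = np.linspace(0, 2 * np.pi, n_stub, endpoint=False)
    ring_pts = np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2
    stub_verts = []
    for t in (0.8 * r, 1.4 * r, 2.0 * r):
        stub_verts.append(t * n_axis[None, :] + stub_r * ring_pts)
    base = len(verts)
    stub_faces = []
    for i in range(2):
        a0 = base + i * n_stub
        b0 = base + (i + 1) * n_stub
        for j in range(n_stub):
            j1 = (j + 1) % n_stub
            stub_faces.append([a0 + j, b0 + j, b0 + j1])
            stub_faces.append([a0 + j, b0 + j1, a0 + j1])
    verts = np.vstack([verts, *stub_verts])
    faces = np.vstack([faces, np.asarray(stub_faces, dtype=np.int64)])
    labels = np.concatenate([labels, np.full(len(stub_faces), int(RegionLabel.OTHER), dtype=np.int8)])
    return LabeledMesh(verts, faces, labels)


def generate_hip(params: HipParams) -> tuple[LabeledMesh, LabeledMesh, GroundTruth]:
    """Emit (pelvis, femur, truth) in the canonical frame (hip center at the
    origin, cup axis +y for defaults).  Fully parametric, hence byte-stable
    for identical parameters; ``seed`` is echoed for provenance."""
    from .mesh_model import orient_consistently

    pelvis, tl = _generate_pelvis(params)
    femur = _generate_femur(params)
    pelvis = orient_consistently(pelvis)
    femur = orient_consistently(femur)
    truth = GroundTruth(
        hip_center=np.zeros(3),
        head_radius=params.head_radius,
        acetabular_radius=params.acetabular_radius,
        fossa_center_direction=_unit(params.fossa_center_direction),
        fossa_angular_radius=params.fossa_angular_radius,
        fovea_direction=_unit(params.fovea_direction),
        fovea_angular_radius=params.fovea_angular_radius,
        lunate_outer_angular_radius=params.lunate_outer_angular_radius,
        transverse_ligament_origin=tl,
        fossa_cap_area=params.cap_area_fossa(),
        fovea_cap_area=params.cap_area_fovea(),
        params=params,
    )
    return pelvis, femur, truth


# -- analytic oracle ---------------------------------------------------


def analytic_ffm(
    params: HipParams,
    protocol: MotionProtocol,
    rom: RomLimits | None = None,
    grid: int = 400,
) -> float:
    """FFM index of ``protocol`` on the ideal sphere-on-sphere geometry.

    Dense rasterization in the medial-view plane: each pixel is lifted to
    the near (y > 0) hemisphere of the acetabular sphere and tested for
    membership in any rotated fovea disc and in the fossa cap; the index is
    the outside fraction of the union's pixel count.  ``grid`` pixels span
    the pattern's larger bounding-box side; the estimate converges as
    O(1/grid) and is resolution-documented in the tests.

    Refuses cam geometry: the oracle is valid only for pure rotations of an
    ideal spherical head.
    """
    if params.cam_bump is not None:
        raise ConfigError("analytic_ffm is valid only for ideal geometry (no cam bump)")
    f = _unit(params.fovea_direction)
    c = _unit(params.fossa_center_direction)
    alpha = np.radians(params.fovea_angular_radius)
    theta_f = np.radians(params.fossa_angular_radius)
    R = params.acetabular_radius

    poses = protocol_poses(protocol)
    dirs = np.asarray([p.rotation @ f for p in poses])
    # discard discs entirely on the far hemisphere (invisible in the view)
    polar = np.arccos(np.clip(dirs[:, 1], -1, 1))
    dirs = dirs[polar - alpha < np.pi / 2]
    if len(dirs) == 0:
        raise NumericalError("no visible fovea footprint for this protocol")

    reach = 2 * R * np.sin(alpha / 2) * 1.1
    lo = np.maximum((dirs[:, [0, 2]] * R).min(axis=0) - reach, -R)
    hi = np.minimum((dirs[:, [0, 2]] * R).max(axis=0) + reach, R)
    res = float(max(hi - lo) / grid)
    xs = np.arange(lo[0] + res / 2, hi[0], res)
    zs = np.arange(lo[1] + res / 2, hi[1], res)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    rho2 = X**2 + Z**2
    on_sphere = rho2 < R**2
    Y = np.sqrt(np.maximum(R**2 - rho2, 0.0))
    Q = np.stack([X, Y, Z], axis=-1) / R  # unit directions, near hemisphere

    cos_a = np.cos(alpha)
    in_union = np.zeros(X.shape, dtype=bool)
    for d in dirs:
        in_union |= Q @ d >= cos_a
    in_union &= on_sphere
    n_union = int(in_union.sum())
    if n_union == 0:
        raise NumericalError("tracking surface empty at this oracle resolution")
    in_fossa = (Q @ c >= np.cos(theta_f)) & on_sphere
    return float((in_union & ~in_fossa).sum() / n_union)


def predicted_cam_contact_angle(
    params: HipParams,
    motion: str = "abduction",
    direction: float = +1.0,
    step: float = 0.5,
) -> float | None:
    """First sweep angle (deg) of an elementary motion at which the cam bump
    contacts the acetabular shell.

    Contact geometry: the bump stands taller than the joint clearance within
    an angular radius ``psi* = sigma * sqrt(2 ln(A / clearance))`` of its
    center, so collision starts when the rotated bump center comes within
    ``lunate_outer + psi*`` of the cup axis.  Returns None if the bump never
    clears the joint space or never reaches the shell within 180 deg.  (With
    the default cup axis along the mediolateral direction, pure flexion —
    a rotation about that axis — never changes bump-shell proximity;
    abduction and axial rotations do.)
    """
    if params.cam_bump is None:
        raise ConfigError("no cam bump in parameters")
    A, sigma = params.cam_bump.amplitude_mm, np.radians(params.cam_bump.extent_deg)
    if A <= params.clearance:
        return None
    psi_star = sigma * np.sqrt(2 * np.log(A / params.clearance))
    limit = np.radians(params.lunate_outer_angular_radius) + psi_star
    loc = _unit(params.cam_bump.location)
    axis = _unit(params.acetabular_center_direction)
    from .kinematics import Branch, compose_rotation

    template = Branch(motion, direction, 0.0)
    for beta in np.arange(0.0, 180.0 + step, step):
        sweep = direction * beta
        angles = {
            "flexion": (sweep, 0.0, 0.0),
            "abduction": (0.0, sweep, 0.0),
            "rotation": (0.0, 0.0, sweep),
        }[template.motion]
        d = compose_rotation(*angles) @ loc
        if np.arccos(np.clip(d @ axis, -1, 1)) <= limit:
            return float(beta)
    return None


# -- synthetic rater data ----------------------------------------------


def generate_rating_table(
    n_subjects: int,
    n_raters: int,
    n_sessions: int,
    subject_sd: float,
    rater_sd: float,
    error_sd: float,
    seed: int,
    motions: list[str] | None = None,
    mean: float = 0.3,
    rater_error_sd=None,
):
    """Two-way random-effects draws y = mu + subject + rater + residual.

    Subject and rater effects are shared across sessions (sessions replicate
    with fresh residuals only), independently per motion.  Returns a
    :class:`ffmkit.reliability.RatingTable`; deterministic given ``seed``.
    ``rater_error_sd`` optionally gives each rater its own residual SD
    (length ``n_raters``), emulating raters of unequal precision.
    """
    from .kinematics import PROTOCOL_ORDER
    from .reliability import RatingTable

    if min(n_subjects, n_raters, n_sessions) < 1:
        raise ConfigError("counts must be positive")
    if min(subject_sd, rater_sd, error_sd) < 0:
        raise ConfigError("standard deviations must be non-negative")
    if motions is None:
        motions = [name for name, _ in PROTOCOL_ORDER]
    if rater_error_sd is None:
        esd = np.full(n_raters, error_sd, dtype=float)
    else:
        esd = np.asarray(rater_error_sd, dtype=float)
        if esd.shape != (n_raters,) or np.any(esd < 0):
            raise ConfigError("rater_error_sd must give one non-negative SD per rater")
    rng = np.random.default_rng(seed)
    rows = []
    for motion in motions:
        subj = rng.normal(0.0, subject_sd, n_subjects)
        rater = rng.normal(0.0, rater_sd, n_raters)
        for i in range(n_subjects):
            for j in range(n_raters):
                for s in range(n_sessions):
                    y = mean + subj[i] + rater[j] + rng.normal(0.0, esd[j])
                    rows.append((i, j, s, motion, y))
    import pandas as pd

    df = pd.DataFrame(rows, columns=["subject", "rater", "session", "motion", "value"])
    return RatingTable(df)
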
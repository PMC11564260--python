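"""Standardized hip coordinate frame.

The frame reproduces the measurement setup: the pelvis is oriented from its
own anatomy (acetabular cup axis from a sphere fit to the lunate surface,
roll fixed by the transverse-ligament origin landmark appearing straight
inferior to the fossa centroid in the medial view), and the femoral head is
translated onto the acetabular sphere center.  In canonical coordinates
(right hip): +x anterior, +y medial, +z cranial, hip center at the origin,
medial view = orthographic projection along +y onto the x-z plane.

Because the frame is derived entirely from the meshes, every downstream
quantity is invariant to rigid pre-transforms of the input pair — the key
correctness property of the standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, NumericalError
from .mesh_model import LabeledMesh, RegionLabel

TL_LANDMARK = "transverse_ligament_origin"


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Solves ``|p|^2 = 2 c.p + (r^2 - |c|^2)`` in the least-squares sense; does
    not require full spherical coverage (a spherical cap suffices as long as
    the points are not coplanar).  Returns (center, radius, rms residual of
    ``|p - c| - r``).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise NumericalError(f"sphere fit needs >= 4 points, got {len(pts)}")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise NumericalError("sphere fit underdetermined: points are coplanar or degenerate")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise NumericalError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def fit_head_sphere(femur: LabeledMesh) -> tuple[np.ndarray, float, float]:
    """Sphere fit over HEAD-labeled vertices (FOVEA and OTHER excluded)."""
    if not femur.has_label(RegionLabel.HEAD):
        raise DataError("femur mesh carries no HEAD label")
    return fit_sphere(femur.region_vertices(RegionLabel.HEAD))


@dataclass
class HipFrame:
    """Coordinate contract for the whole pipeline.

    ``alignment_rotation`` maps input (world) directions into canonical
    directions; meshes returned by :func:`build_hip_frame` are already in
    canonical coordinates with ``hip_center`` at the origin.
    """

    hip_center: np.ndarray
    head_radius: float
    acetabular_radius: float
    axes: np.ndarray  # rows: anteroposterior, mediolateral, craniocaudal (canonical = identity)
    medial_view_direction: np.ndarray
    alignment_rotation: np.ndarray
    head_fit_rms: float = 0.0
    acetabular_fit_rms: float = 0.0
    femur_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def to_dict(self) -> dict:
        return {
            "hip_center_mm": [float(x) for x in self.hip_center],
            "head_radius_mm": float(self.head_radius),
            "acetabular_radius_mm": float(self.acetabular_radius),
            "axes": self.axes.tolist(),
            "medial_view_direction": [float(x) for x in self.medial_view_direction],
            "alignment_rotation": self.alignment_rotation.tolist(),
            "head_fit_rms_mm": float(self.head_fit_rms),
            "acetabular_fit_rms_mm": float(self.acetabular_fit_rms),
        }


def _fossa_centroid(pelvis: LabeledMesh) -> np.ndarray:
    mask = pelvis.label_mask(RegionLabel.FOSSA)
    areas = pelvis.face_areas()[mask]
    cents = pelvis.face_centroids()[mask]
    return (cents * areas[:, None]).sum(axis=0) / areas.sum()


def build_hip_frame(
    pelvis: LabeledMesh,
    femur: LabeledMesh,
    max_sphere_rms: float = 1.5,
) -> tuple[HipFrame, LabeledMesh, LabeledMesh]:
    """Standardize the pair; returns (frame, pelvis', femur'), inputs untouched.

    Steps: sphere fit over LUNATE vertices defines the acetabular center and
    radius; the cup (mediolateral) axis is the direction from that center to
    the lunate centroid; the roll about it is fixed so the fossa-centroid ->
    transverse-ligament-origin vector projects straight inferiorly in the
    medial view; finally the femur is translated so its fitted head center
    coincides with the acetabular center.  Construction is idempotent.
    """
    if not pelvis.has_label(RegionLabel.FOSSA):
        raise DataError("pelvis mesh carries no FOSSA label")
    if not pelvis.has_label(RegionLabel.LUNATE):
        raise DataError("pelvis mesh carries no LUNATE label")
    if TL_LANDMARK not in pelvis.landmarks:
        raise DataError(f"pelvis mesh is missing the {TL_LANDMARK!r} landmark")

    lunate_pts = pelvis.region_vertices(RegionLabel.LUNATE)
    acet_center, acet_radius, acet_rms = fit_sphere(lunate_pts)
    if acet_rms > max_sphere_rms:
        raise NumericalError(
            f"lunate sphere fit residual {acet_rms:.3f} mm exceeds threshold {max_sphere_rms} mm"
        )
    head_center, head_radius, head_rms = fit_head_sphere(femur)
    if head_rms > max_sphere_rms:
        raise NumericalError(
            f"head sphere fit residual {head_rms:.3f} mm exceeds threshold {max_sphere_rms} mm"
        )

    y_axis = lunate_pts.mean(axis=0) - acet_center
    ny = np.linalg.norm(y_axis)
    if ny < 1e-9:
        raise NumericalError("degenerate cup axis: lunate centroid coincides with center")
    y_axis = y_axis / ny

    v = pelvis.landmarks[TL_LANDMARK] - _fossa_centroid(pelvis)
    v_perp = v - (v @ y_axis) * y_axis
    nv = np.linalg.norm(v_perp)
    if nv < 1e-9:
        raise NumericalError(
            "transverse-ligament origin is collinear with the cup axis; roll undefined"
        )
    z_axis = -v_perp / nv
    x_axis = np.cross(y_axis, z_axis)

    R = np.vstack([x_axis, y_axis, z_axis])  # world -> canonical
    pelvis_c = pelvis.transformed(R, -R @ acet_center)
    femur_c = femur.transformed(R, -R @ head_center)

    frame = HipFrame(
        hip_center=np.zeros(3),
        head_radius=head_radius,
        acetabular_radius=acet_radius,
        axes=np.eye(3),
        medial_view_direction=np.array([0.0, 1.0, 0.0]),
        alignment_rotation=R,
        head_fit_rms=head_rms,
        acetabular_fit_rms=acet_rms,
        femur_translation=-R @ head_center,
    )
    return frame, pelvis_c, femur_c
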
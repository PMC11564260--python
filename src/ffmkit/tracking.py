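"""Fovea footprints, medial-view projection, and per-protocol tracking patterns.

The fovea is tracked as a rigid spherical disc: characterized once in
neutral from the FOVEA-labeled vertices (center direction about the hip
center, angular radius containing all fovea vertices), then rotated with
each pose and radially mapped onto the acetabular sphere.  Quantification
happens in the standardized medial view: an orthographic projection along
the mediolateral (+y) axis onto the x-z plane.

Spherical regions are clipped to the hemisphere facing the acetabulum
(y >= 0) before projection; without clipping the orthographic map folds
once an end-range pose carries the disc past the equator.  The analytic
oracle in :mod:`ffmkit.synthetic_hip` applies the identical convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .anatomy_frame import HipFrame
from .errors import DataError
from .kinematics import Pose
from .mesh_model import LabeledMesh, RegionLabel

N_CIRCLE_SEGMENTS = 90  # default discretization of a projected disc boundary
RASTER_RESOLUTION_MM = 0.1


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def project_spherical_cap(
    center_dir: np.ndarray,
    angular_radius_deg: float,
    sphere_radius: float,
    n_segments: int = N_CIRCLE_SEGMENTS,
) -> Polygon | None:
    """Medial-view shadow of a spherical cap, clipped to the y >= 0 hemisphere.

    Returns a simple polygon in mm (x-z plane) or None when the cap lies
    entirely on the far hemisphere.
    """
    d = np.asarray(center_dir, dtype=float)
    d = d / np.linalg.norm(d)
    alpha = np.radians(angular_radius_deg)
    theta_d = np.arccos(np.clip(d[1], -1.0, 1.0))
    R = float(sphere_radius)
    if theta_d - alpha >= np.pi / 2 - 1e-12:
        return None
    u, v = _orthonormal_basis(d)

    def boundary(ts: np.ndarray) -> np.ndarray:
        return R * (
            np.cos(alpha) * d[None, :]
            + np.sin(alpha) * (np.cos(ts)[:, None] * u + np.sin(ts)[:, None] * v)
        )

    if theta_d + alpha <= np.pi / 2 + 1e-12:
        ts = np.linspace(0.0, 2 * np.pi, n_segments, endpoint=False)
        pts = boundary(ts)
        poly = Polygon(np.column_stack([pts[:, 0], pts[:, 2]]))
        return shapely.make_valid(poly) if not poly.is_valid else poly

    # cap straddles the equator: keep the boundary arc with y >= 0 and close
    # the loop along the equator rim (which projects onto the circle |p| = R)
    A = np.sin(alpha) * u[1]
    B = np.sin(alpha) * v[1]
    C = np.cos(alpha) * d[1]
    M = np.hypot(A, B)
    phi = np.arctan2(B, A)
    if M < 1e-15:
        return None
    c = np.clip(-C / M, -1.0, 1.0)
    t0 = np.arccos(c)  # y >= 0 on [phi - t0, phi + t0]
    ts = np.linspace(phi - t0, phi + t0, max(n_segments // 2, 8))
    arc = boundary(ts)
    arc[:, 1] = np.maximum(arc[:, 1], 0.0)

    def rim_angle(p3: np.ndarray) -> float:
        return float(np.arctan2(p3[2], p3[0]))

    psi_end = rim_angle(arc[-1])
    psi_start = rim_angle(arc[0])
    psi_d = float(np.arctan2(d[2], d[0]))
    # walk the rim from the arc's end back to its start, passing through the
    # cap's own azimuth (the equator points inside the cap)
    delta = (psi_start - psi_end) % (2 * np.pi)
    via = (psi_d - psi_end) % (2 * np.pi)
    if via > delta + 1e-12:
        delta -= 2 * np.pi
    psis = psi_end + np.linspace(0.0, delta, max(n_segments // 2, 8))
    rim = np.column_stack([R * np.cos(psis), R * np.sin(psis)])
    xy = np.vstack([np.column_stack([arc[:, 0], arc[:, 2]]), rim[1:-1]])
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = shapely.make_valid(poly).buffer(0)
        if poly.geom_type != "Polygon":
            poly = max(poly.geoms, key=lambda g: g.area) if hasattr(poly, "geoms") else poly
    return poly if poly.area > 0 else None


# -- fovea characterization and footprints ------------------------------


def characterize_fovea(femur: LabeledMesh, frame: HipFrame) -> tuple[np.ndarray, float]:
    """Neutral fovea disc (center direction, angular radius in degrees) from
    the FOVEA-face vertex directions about the hip center; the radius is the
    angular extent containing all fovea vertices."""
    if not femur.has_label(RegionLabel.FOVEA):
        raise DataError("femur mesh carries no FOVEA label")
    pts = femur.region_vertices(RegionLabel.FOVEA) - frame.hip_center
    dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    center = dirs.mean(axis=0)
    center /= np.linalg.norm(center)
    cosang = np.clip(dirs @ center, -1.0, 1.0)
    return center, float(np.degrees(np.arccos(cosang.min())))


@dataclass
class Footprint:
    """One pose's fovea footprint on the acetabular sphere."""

    pose: Pose
    center_dir: np.ndarray
    angular_radius_deg: float
    sphere_radius: float
    polygon: Polygon | None

    def spherical_area(self) -> float:
        """Area of the full spherical disc (pose independent: rigid motion
        preserves it)."""
        a = np.radians(self.angular_radius_deg)
        return float(2 * np.pi * self.sphere_radius**2 * (1 - np.cos(a)))


def fovea_footprint(
    femur: LabeledMesh,
    pose: Pose,
    frame: HipFrame,
    fovea: tuple[np.ndarray, float] | None = None,
    n_segments: int = N_CIRCLE_SEGMENTS,
) -> Footprint:
    """Footprint of the fovea disc at ``pose``, radially mapped onto the
    acetabular sphere and projected into the medial view."""
    center, radius_deg = fovea if fovea is not None else characterize_fovea(femur, frame)
    rotated = pose.rotation @ center
    poly = project_spherical_cap(rotated, radius_deg, frame.acetabular_radius, n_segments)
    return Footprint(pose, rotated, radius_deg, frame.acetabular_radius, poly)


# -- fossa outline -----------------------------------------------------


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    counts: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], tuple[int, int]] = {}
    for tri in faces:
        for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(min(e)), int(max(e)))
            counts[key] = counts.get(key, 0) + 1
            directed[key] = (int(e[0]), int(e[1]))
    border = [directed[k] for k, c in counts.items() if c == 1]
    nxt = {a: b for a, b in border}
    loops: list[list[int]] = []
    seen: set[int] = set()
    for a, _ in border:
        if a in seen:
            continue
        loop = [a]
        seen.add(a)
        cur = nxt.get(a)
        while cur is not None and cur != a:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        loops.append(loop)
    return loops


def fossa_region_2d(pelvis: LabeledMesh, frame: HipFrame) -> Polygon:
    """Projected outline of the acetabular fossa in the medial view.

    Extracts the single closed boundary loop of the FOSSA face set and
    projects it along the medial-view direction; errors if the fossa
    boundary is not one loop.
    """
    if not pelvis.has_label(RegionLabel.FOSSA):
        raise DataError("pelvis mesh carries no FOSSA label")
    faces = pelvis.faces[pelvis.label_mask(RegionLabel.FOSSA)]
    loops = _boundary_loops(faces)
    if len(loops) != 1:
        raise DataError(f"fossa boundary is not a single closed loop (found {len(loops)})")
    pts = pelvis.vertices[loops[0]]
    poly = Polygon(np.column_stack([pts[:, 0], pts[:, 2]]))
    if not poly.is_valid:
        poly = shapely.make_valid(poly).buffer(0)
    if poly.is_empty or poly.area <= 0:
        raise DataError("projected fossa outline has zero area")
    return poly


# -- tracking patterns -------------------------------------------------


@dataclass
class TrackingPattern:
    """Union of footprints in the medial view, partitioned by the fossa."""

    protocol: str
    union_region: Polygon
    fossa_region: Polygon
    area_total: float
    area_inside: float
    area_outside: float
    backend: str = "polygon"
    resolution_mm: float = RASTER_RESOLUTION_MM

    def spherical_area_total(self, sphere_radius: float) -> float:
        """Spherical surface area of the tracked union, recovered from the
        projection by the inverse-foreshortening weight R/|y| (reported for
        research use; the FFM index itself is the 2D projected ratio)."""
        return _raster_spherical_area(self.union_region, sphere_radius, self.resolution_mm)


def _raster_spherical_area(region: Polygon, R: float, res: float) -> float:
    minx, minz, maxx, maxz = region.bounds
    xs = np.arange(minx + res / 2, maxx, res)
    zs = np.arange(minz + res / 2, maxz, res)
    if not len(xs) or not len(zs):
        return 0.0
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    inside = shapely.contains_xy(region, X.ravel(), Z.ravel()).reshape(X.shape)
    rho2 = X**2 + Z**2
    y = np.sqrt(np.maximum(R**2 - rho2, 1e-12))
    w = np.where(inside & (rho2 < R**2), R / y, 0.0)
    return float(w.sum() * res * res)


def tracking_pattern(
    footprints,
    fossa2d: Polygon,
    resolution: float = RASTER_RESOLUTION_MM,
    backend: str = "polygon",
    protocol: str = "",
) -> TrackingPattern:
    """Union the projected footprints and partition by the fossa outline.

    ``backend='polygon'`` uses exact polygon booleans (default);
    ``backend='raster'`` rasterizes at ``resolution`` mm (fallback, and the
    cross-check for the boolean path).
    """
    polys = [fp.polygon for fp in footprints if fp.polygon is not None and fp.polygon.area > 0]
    if not polys:
        raise DataError("no footprints with a visible (near-hemisphere) projection")
    union = unary_union(polys)
    if union.area <= 0:
        raise DataError("tracking pattern has zero area")
    if backend == "polygon":
        inside = union.intersection(fossa2d).area
        outside = union.difference(fossa2d).area
        total = union.area
    elif backend == "raster":
        minx, minz, maxx, maxz = union.bounds
        xs = np.arange(minx - resolution, maxx + resolution, resolution)
        zs = np.arange(minz - resolution, maxz + resolution, resolution)
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        in_union = shapely.contains_xy(union, X.ravel(), Z.ravel())
        in_fossa = shapely.contains_xy(fossa2d, X.ravel(), Z.ravel())
        cell = resolution * resolution
        total = float(in_union.sum() * cell)
        inside = float((in_union & in_fossa).sum() * cell)
        outside = float((in_union & ~in_fossa).sum() * cell)
        if total <= 0:
            raise DataError("tracking pattern has zero area at this raster resolution")
    else:
        raise DataError(f"unknown tracking backend {backend!r}")
    return TrackingPattern(
        protocol=protocol,
        union_region=union,
        fossa_region=fossa2d,
        area_total=float(total),
        area_inside=float(inside),
        area_outside=float(outside),
        backend=backend,
        resolution_mm=resolution,
    )


# -- SVG export --------------------------------------------------------


def _poly_paths(geom) -> list[np.ndarray]:
    if geom.is_empty:
        return []
    geoms = geom.geoms if hasattr(geom, "geoms") else [geom]
    out = []
    for g in geoms:
        if g.geom_type == "Polygon":
            out.append(np.asarray(g.exterior.coords))
    return out


def pattern_to_svg(pattern: TrackingPattern, path) -> None:
    """Medial-view overlay: fossa outline, inside (dark) / outside (light)
    shading of the tracking pattern."""
    fossa = pattern.fossa_region
    inside = pattern.union_region.intersection(fossa)
    outside = pattern.union_region.difference(fossa)
    all_geoms = _poly_paths(fossa) + _poly_paths(inside) + _poly_paths(outside)
    pts = np.vstack(all_geoms) if all_geoms else np.zeros((1, 2))
    minx, minz = pts.min(axis=0) - 2
    maxx, maxz = pts.max(axis=0) + 2
    w, h = maxx - minx, maxz - minz

    def path_d(coords: np.ndarray) -> str:
        # flip z so cranial points up in the figure
        s = " L ".join(f"{x - minx:.3f} {maxz - z:.3f}" for x, z in coords)
        return f"M {s} Z"

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {w:.3f} {h:.3f}" '
        f'width="{w * 10:.0f}" height="{h * 10:.0f}">',
        f'<title>{pattern.protocol}</title>',
    ]
    for coords in _poly_paths(fossa):
        parts.append(f'<path d="{path_d(coords)}" fill="#f2e8d5" stroke="#8a6d3b" stroke-width="0.3"/>')
    for coords in _poly_paths(inside):
        parts.append(f'<path d="{path_d(coords)}" fill="#4a7fb5" fill-opacity="0.8" stroke="none"/>')
    for coords in _poly_paths(outside):
        parts.append(f'<path d="{path_d(coords)}" fill="#c0504d" fill-opacity="0.8" stroke="none"/>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
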
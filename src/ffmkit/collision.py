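"""Femoro-pelvic collision detection and motion-branch truncation.

Narrow phase: exact triangle-triangle intersection built from
segment-through-triangle tests (Moller-Trumbore) plus a coplanar-overlap
fallback; with a positive tolerance the test becomes a triangle-triangle
minimum-distance threshold.  Broad phase: a KD-tree over triangle centroids
with conservative circumradius bounds, so the accelerated result is
identical to exhaustive all-pairs testing.

Articular proximity is not impingement: candidate face pairs whose labels
are {HEAD, LUNATE} (the permanently near-contact bearing surfaces) are
excluded by default; only extra-articular and fossa/fovea-rim contacts
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError
from .mesh_model import LabeledMesh, RegionLabel

DEFAULT_EXCLUDED_PAIRS = frozenset({frozenset({RegionLabel.HEAD, RegionLabel.LUNATE})})

_EPS = 1e-12


# -- narrow phase ------------------------------------------------------


def _seg_tri_hit(p0: np.ndarray, p1: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorized segment-triangle intersection (inclusive boundaries).

    p0, p1 : (n, 3); tri : (n, 3, 3)  ->  bool (n,)
    """
    d = p1 - p0
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1) * np.linalg.norm(d, axis=1)
    ok = np.abs(a) > _EPS * np.maximum(scale, _EPS)
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = p0 - tri[:, 0]
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("ij,ij->i", d, q)
    t = f * np.einsum("ij,ij->i", e2, q)
    tol = 1e-9
    return ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t >= -tol) & (t <= 1 + tol)


def _coplanar_overlap_2d(ta: np.ndarray, tb: np.ndarray) -> bool:
    """Separating-axis overlap test for two coplanar triangles (scalar)."""
    n = np.cross(ta[1] - ta[0], ta[2] - ta[0])
    k = int(np.argmax(np.abs(n)))
    cols = [c for c in range(3) if c != k]
    A, B = ta[:, cols], tb[:, cols]
    for tri in (A, B):
        for i in range(3):
            edge = tri[(i + 1) % 3] - tri[i]
            axis = np.array([-edge[1], edge[0]])
            pa, pb = A @ axis, B @ axis
            if pa.max() < pb.min() - _EPS or pb.max() < pa.min() - _EPS:
                return False
    return True


def tri_tri_intersect(ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """Exact intersection test for paired triangle arrays (n, 3, 3)."""
    ta = np.asarray(ta, dtype=float).reshape(-1, 3, 3)
    tb = np.asarray(tb, dtype=float).reshape(-1, 3, 3)
    hit = np.zeros(len(ta), dtype=bool)
    for i in range(3):
        j = (i + 1) % 3
        hit |= _seg_tri_hit(ta[:, i], ta[:, j], tb)
        hit |= _seg_tri_hit(tb[:, i], tb[:, j], ta)
    # coplanar pairs can overlap without any edge passing through the interior
    nb = np.cross(tb[:, 1] - tb[:, 0], tb[:, 2] - tb[:, 0])
    nbn = np.linalg.norm(nb, axis=1)
    dist = np.abs(np.einsum("nij,nj->ni", ta - tb[:, :1], nb)) / np.maximum(nbn, _EPS)[:, None]
    size = np.maximum(nbn, 1.0)
    maybe_cop = (~hit) & (dist.max(axis=1) < 1e-9 * np.sqrt(size))
    for idx in np.nonzero(maybe_cop)[0]:
        if _coplanar_overlap_2d(ta[idx], tb[idx]):
            hit[idx] = True
    return hit


def _point_seg_dist2(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.einsum("ij,ij->i", p - a, ab) / np.maximum(np.einsum("ij,ij->i", ab, ab), _EPS)
    t = np.clip(t, 0.0, 1.0)
    d = p - (a + t[:, None] * ab)
    return np.einsum("ij,ij->i", d, d)


def _point_tri_dist2(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nn = np.maximum(np.einsum("ij,ij->i", n, n), _EPS)
    w = p - tri[:, 0]
    t = np.einsum("ij,ij->i", w, n) / nn
    proj = p - t[:, None] * n
    # barycentric test of the projection
    v0 = tri[:, 1] - tri[:, 0]
    v1 = tri[:, 2] - tri[:, 0]
    v2 = proj - tri[:, 0]
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = np.maximum(d00 * d11 - d01 * d01, _EPS)
    bv = (d11 * d20 - d01 * d21) / denom
    bw = (d00 * d21 - d01 * d20) / denom
    inside = (bv >= 0) & (bw >= 0) & (bv + bw <= 1)
    dp = p - proj
    plane2 = np.einsum("ij,ij->i", dp, dp)
    edge2 = np.minimum.reduce(
        [
            _point_seg_dist2(p, tri[:, 0], tri[:, 1]),
            _point_seg_dist2(p, tri[:, 1], tri[:, 2]),
            _point_seg_dist2(p, tri[:, 2], tri[:, 0]),
        ]
    )
    return np.where(inside, plane2, edge2)


def _seg_seg_dist2(p1, q1, p2, q2) -> np.ndarray:
    """Vectorized squared distance between segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = np.maximum(a * e - b * b, _EPS)
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0)
    t = (b * s + f) / np.maximum(e, _EPS)
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t_cl - c) / np.maximum(a, _EPS), 0.0, 1.0)
    cp1 = p1 + s[:, None] * d1
    cp2 = p2 + t_cl[:, None] * d2
    d = cp1 - cp2
    return np.einsum("ij,ij->i", d, d)


def tri_tri_distance(ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """Minimum distance between paired triangles (0 where intersecting)."""
    ta = np.asarray(ta, dtype=float).reshape(-1, 3, 3)
    tb = np.asarray(tb, dtype=float).reshape(-1, 3, 3)
    d2 = np.full(len(ta), np.inf)
    for i in range(3):
        d2 = np.minimum(d2, _point_tri_dist2(ta[:, i], tb))
        d2 = np.minimum(d2, _point_tri_dist2(tb[:, i], ta))
        for j in range(3):
            d2 = np.minimum(
                d2,
                _seg_seg_dist2(
                    ta[:, i], ta[:, (i + 1) % 3], tb[:, j], tb[:, (j + 1) % 3]
                ),
            )
    dist = np.sqrt(d2)
    dist[tri_tri_intersect(ta, tb)] = 0.0
    return dist


# -- broad phase + public API ------------------------------------------


@dataclass
class CollisionReport:
    collided: bool
    contact_point: np.ndarray | None = None
    face_pair: tuple[int, int] | None = None
    n_candidate_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "collided": bool(self.collided),
            "contact_point_mm": None if self.contact_point is None else [float(x) for x in self.contact_point],
            "face_pair": None if self.face_pair is None else [int(self.face_pair[0]), int(self.face_pair[1])],
            "n_candidate_pairs": int(self.n_candidate_pairs),
        }


def _candidate_pairs(tri_a, tri_b, tolerance: float) -> tuple[np.ndarray, np.ndarray]:
    ca = tri_a.mean(axis=1)
    cb = tri_b.mean(axis=1)
    ra = np.linalg.norm(tri_a - ca[:, None, :], axis=2).max(axis=1)
    rb = np.linalg.norm(tri_b - cb[:, None, :], axis=2).max(axis=1)
    tree_b = cKDTree(cb)
    lists = tree_b.query_ball_point(ca, r=ra + rb.max() + tolerance)
    lens = np.fromiter((len(l) for l in lists), dtype=int, count=len(lists))
    ia = np.repeat(np.arange(len(lists)), lens)
    ib = np.fromiter((j for l in lists for j in l), dtype=int, count=int(lens.sum()))
    if ia.size:
        keep = np.linalg.norm(ca[ia] - cb[ib], axis=1) <= ra[ia] + rb[ib] + tolerance
        ia, ib = ia[keep], ib[keep]
    return ia, ib


def meshes_collide(
    mesh_a: LabeledMesh,
    mesh_b: LabeledMesh,
    tolerance: float = 0.0,
    excluded_label_pairs=DEFAULT_EXCLUDED_PAIRS,
    exhaustive: bool = False,
) -> CollisionReport:
    """True iff any (non-excluded) triangle pair intersects or approaches
    within ``tolerance`` mm.  ``exhaustive=True`` bypasses the spatial index
    (oracle path for equivalence checks)."""
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        raise DataError("collision test on empty mesh")
    tri_a = mesh_a.triangles()
    tri_b = mesh_b.triangles()
    if exhaustive:
        ia, ib = np.meshgrid(np.arange(mesh_a.n_faces), np.arange(mesh_b.n_faces), indexing="ij")
        ia, ib = ia.ravel(), ib.ravel()
    else:
        ia, ib = _candidate_pairs(tri_a, tri_b, tolerance)
    if ia.size and excluded_label_pairs:
        la = mesh_a.face_labels[ia]
        lb = mesh_b.face_labels[ib]
        mask = np.ones(len(ia), dtype=bool)
        for pair in excluded_label_pairs:
            pp = sorted(pair)
            p0, p1 = int(pp[0]), int(pp[-1])
            mask &= ~(((la == p0) & (lb == p1)) | ((la == p1) & (lb == p0)))
        ia, ib = ia[mask], ib[mask]
    n_cand = int(ia.size)
    if not n_cand:
        return CollisionReport(False, n_candidate_pairs=0)
    if tolerance > 0:
        dist = tri_tri_distance(tri_a[ia], tri_b[ib])
        hits = dist <= tolerance
    else:
        hits = tri_tri_intersect(tri_a[ia], tri_b[ib])
    if not hits.any():
        return CollisionReport(False, n_candidate_pairs=n_cand)
    k = int(np.nonzero(hits)[0][0])
    fa, fb = int(ia[k]), int(ib[k])
    contact = 0.5 * (tri_a[fa].mean(axis=0) + tri_b[fb].mean(axis=0))
    return CollisionReport(True, contact_point=contact, face_pair=(fa, fb), n_candidate_pairs=n_cand)


@dataclass
class BranchCollisionReport:
    pose_collided: list[bool]
    first_colliding_step: int | None
    contacts: list[CollisionReport] = field(default_factory=list)


def truncate_at_impingement(
    poses,
    pelvis: LabeledMesh,
    femur: LabeledMesh,
    tolerance: float = 0.0,
    excluded_label_pairs=DEFAULT_EXCLUDED_PAIRS,
):
    """Walk a neutral-outward branch; exclude the first colliding pose and
    everything beyond it.

    The anatomical neutral (identity rotation, step 0) must be collision
    free — a colliding neutral means the geometry or clearance is invalid
    and raises.  A pre-rotated branch (impingement tests start at a fixed
    flexed pose) may collide at its step 0; it is then truncated to empty.
    Returns (admissible_poses, BranchCollisionReport).
    """
    admissible = []
    flags: list[bool] = []
    contacts: list[CollisionReport] = []
    first = None
    for i, pose in enumerate(poses):
        femur_at = femur.transformed(pose.rotation)
        rep = meshes_collide(femur_at, pelvis, tolerance, excluded_label_pairs)
        flags.append(rep.collided)
        contacts.append(rep)
        if rep.collided:
            if i == 0 and np.allclose(pose.rotation, np.eye(3), atol=1e-12):
                loc = rep.contact_point
                raise DataError(
                    "neutral pose already collides (invalid geometry or clearance); "
                    f"contact near {None if loc is None else np.round(loc, 2).tolist()}"
                )
            first = i
            break
        admissible.append(pose)
    return admissible, BranchCollisionReport(flags, first, contacts)
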
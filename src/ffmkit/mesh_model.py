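"""Labeled triangle meshes of the hip and their anatomical regions.

A :class:`LabeledMesh` is a plain triangle surface (vertices in millimetres,
0-based face indices) carrying one anatomical :class:`RegionLabel` per face
plus named point landmarks.  Mesh geometry travels in the usual surface
formats (STL, PLY, OBJ); because STL carries no attributes, labels and
landmarks live in a JSON sidecar (see :data:`SIDECAR_SCHEMA`).

Non-watertight meshes are accepted throughout: open hemipelvis cuts are
normal for clinical segmentations.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .errors import DataError

SIDECAR_SCHEMA = "ffmkit-labels-1"


class RegionLabel(IntEnum):
    """Controlled vocabulary of anatomical regions.

    FOSSA appears only on the pelvis; HEAD and FOVEA only on the femur.
    """

    LUNATE = 0
    FOSSA = 1
    HEAD = 2
    FOVEA = 3
    OTHER = 4


_LABEL_NAMES = {lab.name: lab for lab in RegionLabel}


@dataclass
class LabeledMesh:
    """Triangle surface with per-face anatomical region labels.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of 0-based vertex indices.
    face_labels : (m,) int array of :class:`RegionLabel` codes.
    landmarks : mapping of landmark name to 3D point (mm).
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.face_labels = np.asarray(self.face_labels, dtype=np.int8).reshape(-1)
        if len(self.face_labels) != len(self.faces):
            raise DataError(
                f"face_labels length {len(self.face_labels)} != face count {len(self.faces)}"
            )
        bad = np.nonzero((self.faces < 0) | (self.faces >= len(self.vertices)))[0]
        if bad.size:
            f = int(bad[0])
            raise DataError(
                f"face {f} references vertex index {int(self.faces.reshape(-1)[f])} "
                f"outside [0, {len(self.vertices)})"
            )
        valid = {int(v) for v in RegionLabel}
        unknown = set(np.unique(self.face_labels)) - valid
        if unknown:
            raise DataError(f"unknown region label code(s): {sorted(unknown)}")
        self.landmarks = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()}

    # -- basic queries -------------------------------------------------

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def label_mask(self, label: RegionLabel) -> np.ndarray:
        return self.face_labels == int(label)

    def has_label(self, label: RegionLabel) -> bool:
        return bool(self.label_mask(label).any())

    def region_vertices(self, label: RegionLabel) -> np.ndarray:
        """Coordinates of vertices referenced by faces carrying ``label``."""
        idx = np.unique(self.faces[self.label_mask(label)])
        return self.vertices[idx]

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.face_labels.copy(),
            {k: v.copy() for k, v in self.landmarks.items()},
        )

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "LabeledMesh":
        """Return a rigidly transformed copy: p -> R p + t (landmarks included)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        out = self.copy()
        out.vertices = out.vertices @ R.T + t
        out.landmarks = {k: R @ v + t for k, v in out.landmarks.items()}
        return out

    def mirrored_sagittal(self) -> "LabeledMesh":
        """Mirror a left hip across the sagittal (x-z) plane into the right-hip
        convention, restoring face winding afterwards."""
        out = self.copy()
        out.vertices[:, 1] *= -1.0
        out.faces = out.faces[:, ::-1]
        out.landmarks = {k: v * np.array([1.0, -1.0, 1.0]) for k, v in out.landmarks.items()}
        return out


# -- region extraction -------------------------------------------------


def extract_region(mesh: LabeledMesh, label: RegionLabel, complement: bool = False) -> LabeledMesh:
    """Submesh of exactly the faces carrying ``label`` (vertices reindexed).

    With ``complement=True`` every face *not* carrying the label is returned
    instead; this is the operation that implements digital removal of the
    acetabular fossa (keep everything but FOSSA).
    """
    mask = mesh.label_mask(label)
    if not mask.any():
        raise DataError(f"label {RegionLabel(label).name} absent from mesh")
    if complement:
        mask = ~mask
    faces = mesh.faces[mask]
    labels = mesh.face_labels[mask]
    used, inverse = np.unique(faces, return_inverse=True)
    return LabeledMesh(
        mesh.vertices[used],
        inverse.reshape(-1, 3),
        labels,
        {k: v.copy() for k, v in mesh.landmarks.items()},
    )


# -- validation --------------------------------------------------------


@dataclass
class ValidationReport:
    n_vertices: int
    n_faces: int
    degenerate_faces: list[int]
    non_manifold_edges: int
    boundary_edges: int
    label_coverage: dict[str, float]
    disconnected_regions: list[str]
    bounding_box: np.ndarray  # (2, 3) min/max
    passed: bool


def _edge_counts(faces: np.ndarray) -> dict[tuple[int, int], int]:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    counts: dict[tuple[int, int], int] = {}
    for a, b in edges:
        key = (int(a), int(b))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _region_components(mesh: LabeledMesh, label: RegionLabel) -> int:
    """Number of edge-connected components of the faces carrying ``label``."""
    idx = np.nonzero(mesh.label_mask(label))[0]
    if idx.size == 0:
        return 0
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for f in idx:
        a, b, c = mesh.faces[f]
        for e in ((a, b), (b, c), (c, a)):
            key = (int(min(e)), int(max(e)))
            edge_to_faces.setdefault(key, []).append(int(f))
    parent = {int(f): int(f) for f in idx}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for flist in edge_to_faces.values():
        for other in flist[1:]:
            ra, rb = find(flist[0]), find(other)
            if ra != rb:
                parent[ra] = rb
    return len({find(int(f)) for f in idx})


def validate_mesh(mesh: LabeledMesh, area_tol: float = 1e-12, strict: bool = False) -> ValidationReport:
    """Report mesh defects and label coverage; pass/fail per policy.

    The default policy fails only on degenerate faces and (if ``strict``)
    non-manifold edges; boundary edges are always allowed because clinical
    shells are open surfaces.
    """
    areas = mesh.face_areas()
    degenerate = np.nonzero(areas <= area_tol)[0].tolist()
    counts = _edge_counts(mesh.faces)
    non_manifold = sum(1 for c in counts.values() if c > 2)
    boundary = sum(1 for c in counts.values() if c == 1)
    total = max(mesh.n_faces, 1)
    coverage = {
        lab.name: float(np.count_nonzero(mesh.face_labels == int(lab))) / total
        for lab in RegionLabel
        if np.any(mesh.face_labels == int(lab))
    }
    disconnected = [
        lab.name
        for lab in RegionLabel
        if mesh.has_label(lab) and _region_components(mesh, lab) > 1
    ]
    passed = not degenerate and (not strict or non_manifold == 0)
    bbox = np.vstack([mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)]) if len(mesh.vertices) else np.zeros((2, 3))
    return ValidationReport(
        n_vertices=len(mesh.vertices),
        n_faces=mesh.n_faces,
        degenerate_faces=degenerate,
        non_manifold_edges=non_manifold,
        boundary_edges=boundary,
        label_coverage=coverage,
        disconnected_regions=disconnected,
        bounding_box=bbox,
        passed=passed,
    )


def drop_degenerate_faces(mesh: LabeledMesh, area_tol: float = 1e-12) -> LabeledMesh:
    keep = mesh.face_areas() > area_tol
    return LabeledMesh(mesh.vertices, mesh.faces[keep], mesh.face_labels[keep], mesh.landmarks)


def orient_consistently(mesh: LabeledMesh) -> LabeledMesh:
    """Flip faces so winding agrees across shared edges within each connected
    component, then orient each component so its mean normal points away from
    the mesh centroid (outward for convex-ish shells)."""
    faces = mesh.faces.copy()
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for f in range(len(faces)):
        a, b, c = faces[f]
        for e in ((a, b), (b, c), (c, a)):
            key = (int(min(e)), int(max(e)))
            edge_to_faces.setdefault(key, []).append(f)
    visited = np.zeros(len(faces), dtype=bool)
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        comp = [seed]
        while stack:
            f = stack.pop()
            fa, fb, fc = faces[f]
            directed = {(int(fa), int(fb)), (int(fb), int(fc)), (int(fc), int(fa))}
            for e in list(directed):
                key = (min(e), max(e))
                for g in edge_to_faces[key]:
                    if g == f or visited[g]:
                        continue
                    ga, gb, gc = faces[g]
                    gdir = {(int(ga), int(gb)), (int(gb), int(gc)), (int(gc), int(ga))}
                    # consistent winding: shared edge traversed in opposite directions
                    if e in gdir:
                        faces[g] = faces[g][::-1]
                    visited[g] = True
                    comp.append(g)
                    stack.append(g)
        # orient the component outward relative to its own centroid
        tri = mesh.vertices[faces[comp]]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centroids = tri.mean(axis=1)
        outward = centroids - centroids.mean(axis=0)
        if float(np.einsum("ij,ij->i", normals, outward).sum()) < 0:
            faces[comp] = faces[comp][:, ::-1]
    return LabeledMesh(mesh.vertices, faces, mesh.face_labels, mesh.landmarks)


# -- geometry file I/O -------------------------------------------------


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid" and b"facet" in raw[:2048]
    if is_ascii:
        tris = []
        cur: list[list[float]] = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if parts[:1] == ["vertex"]:
                cur.append([float(x) for x in parts[1:4]])
                if len(cur) == 3:
                    tris.append(cur)
                    cur = []
        soup = np.asarray(tris, dtype=float)
    else:
        if len(raw) < 84:
            raise DataError(f"{path}: truncated binary STL")
        (n,) = struct.unpack_from("<I", raw, 80)
        need = 84 + 50 * n
        if len(raw) < need:
            raise DataError(f"{path}: binary STL declares {n} facets but file is short")
        rec = np.frombuffer(raw, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
        soup = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(float)
    if soup.size == 0:
        raise DataError(f"{path}: STL contains no facets")
    # weld the triangle soup back into an indexed mesh
    flat = np.round(soup.reshape(-1, 3), 6)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    return verts, inverse.reshape(-1, 3)


def _write_stl(path: Path, mesh: LabeledMesh, binary: bool = False) -> None:
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    if binary:
        buf = bytearray(b"\0" * 80)
        buf += struct.pack("<I", len(tri))
        for i in range(len(tri)):
            buf += struct.pack("<3f", *n[i])
            for v in tri[i]:
                buf += struct.pack("<3f", *v)
            buf += b"\0\0"
        path.write_bytes(bytes(buf))
        return
    lines = ["solid ffmkit"]
    for i in range(len(tri)):
        lines.append(f"  facet normal {n[i, 0]:.9e} {n[i, 1]:.9e} {n[i, 2]:.9e}")
        lines.append("    outer loop")
        for v in tri[i]:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid ffmkit\n")
    path.write_text("\n".join(lines))


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise DataError(f"{path}: not a PLY file")
    n_v = n_f = 0
    i = 1
    fmt = None
    while i < len(text):
        parts = text[i].split()
        if parts[:1] == ["format"]:
            fmt = parts[1]
        elif parts[:2] == ["element", "vertex"]:
            n_v = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_f = int(parts[2])
        elif parts[:1] == ["end_header"]:
            i += 1
            break
        i += 1
    if fmt != "ascii":
        raise DataError(f"{path}: only ASCII PLY is supported (got {fmt})")
    verts = np.array([[float(x) for x in text[i + j].split()[:3]] for j in range(n_v)])
    faces = []
    for j in range(n_f):
        parts = text[i + n_v + j].split()
        if int(parts[0]) != 3:
            raise DataError(f"{path}: face {j} is not a triangle")
        faces.append([int(x) for x in parts[1:4]])
    return verts, np.asarray(faces, dtype=np.int64)


def _write_ply(path: Path, mesh: LabeledMesh) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}" for v in mesh.vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            if len(idx) != 3:
                raise DataError(f"{path}: OBJ face with {len(idx)} vertices (triangles only)")
            faces.append(idx)
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def _write_obj(path: Path, mesh: LabeledMesh) -> None:
    lines = [f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}" for v in mesh.vertices]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


# -- sidecar I/O -------------------------------------------------------


def _ranges_from_labels(labels: np.ndarray) -> dict[str, list[list[int]]]:
    out: dict[str, list[list[int]]] = {}
    if len(labels) == 0:
        return out
    starts = np.r_[0, np.nonzero(np.diff(labels) != 0)[0] + 1]
    stops = np.r_[starts[1:], len(labels)]
    for s, e in zip(starts, stops):
        name = RegionLabel(int(labels[s])).name
        out.setdefault(name, []).append([int(s), int(e)])
    return out


def write_sidecar(path: Path, mesh: LabeledMesh) -> None:
    doc = {
        "schema": SIDECAR_SCHEMA,
        "n_faces": mesh.n_faces,
        "face_labels": _ranges_from_labels(mesh.face_labels),
        "landmarks": {k: [float(x) for x in v] for k, v in mesh.landmarks.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_sidecar(path: Path, n_faces: int) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise DataError(f"{path}: sidecar is not valid JSON ({e})") from e
    labels = np.full(n_faces, -1, dtype=np.int8)
    for name, ranges in doc.get("face_labels", {}).items():
        if name not in _LABEL_NAMES:
            raise DataError(f"{path}: unknown label token {name!r}")
        for rng in ranges:
            s, e = int(rng[0]), int(rng[1])
            if s < 0 or e > n_faces or s >= e:
                raise DataError(
                    f"{path}: label {name} range [{s}, {e}) out of bounds for {n_faces} faces"
                )
            labels[s:e] = int(_LABEL_NAMES[name])
    if np.any(labels < 0):
        first = int(np.nonzero(labels < 0)[0][0])
        raise DataError(f"{path}: face {first} has no label assignment")
    landmarks = {k: np.asarray(v, dtype=float) for k, v in doc.get("landmarks", {}).items()}
    return labels, landmarks


# -- public load/save --------------------------------------------------

_READERS = {".stl": _read_stl, ".ply": _read_ply, ".obj": _read_obj}


def load_labeled_mesh(path, label_path, clean: bool = True) -> LabeledMesh:
    """Load mesh geometry plus its JSON label sidecar into a validated
    :class:`LabeledMesh` (units mm, winding made consistent)."""
    path = Path(path)
    reader = _READERS.get(path.suffix.lower())
    if reader is None:
        raise DataError(f"{path}: unsupported mesh format {path.suffix!r} (STL/PLY/OBJ)")
    try:
        verts, faces = reader(path)
    except (OSError, ValueError, IndexError) as e:
        raise DataError(f"{path}: unreadable mesh file ({e})") from e
    labels, landmarks = read_sidecar(label_path, len(faces))
    mesh = LabeledMesh(verts, faces, labels, landmarks)
    mesh = orient_consistently(mesh)
    if clean:
        mesh = drop_degenerate_faces(mesh)
    return mesh


def save_labeled_mesh(mesh: LabeledMesh, path, label_path=None, binary_stl: bool = False) -> None:
    """Write geometry (format chosen by extension) and the label sidecar.

    Note STL stores an unindexed triangle soup: vertex order and indexing are
    not preserved through an STL round-trip, only per-face coordinates
    (welded back on load at 1e-6 mm precision).  PLY/OBJ round-trip exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".stl":
        _write_stl(path, mesh, binary=binary_stl)
    elif path.suffix.lower() == ".ply":
        _write_ply(path, mesh)
    elif path.suffix.lower() == ".obj":
        _write_obj(path, mesh)
    else:
        raise DataError(f"{path}: unsupported mesh format {path.suffix!r} (STL/PLY/OBJ)")
    if label_path is None:
        label_path = path.with_suffix(".labels.json")
    write_sidecar(Path(label_path), mesh)
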
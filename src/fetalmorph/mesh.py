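"""Surface-mesh primitives shared by every pipeline stage.

Meshes are triangulated open (or closed) surfaces in world millimetres.
The canonical frame, fixed by :func:`landmark_align` against a reference
landmark set, is y-up with the face looking towards +z.  Triangle winding
is counter-clockwise seen from outside, so outward normals follow the
right-hand rule on vertex order; :func:`cut_mesh` relies on this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "RigidTransform",
    "CuttingPlane",
    "MeshFormatError",
    "DegenerateGeometryError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "landmark_align",
    "icp_align",
    "cut_mesh",
    "cell_geometry",
    "remesh_isotropic",
]

LANDMARK_NAMES = ("left_eye", "right_eye", "nose", "lip_midpoint")

_MERGE_TOL = 1e-9  # mm; vertices closer than this are considered duplicates
_AREA_TOL = 1e-12  # mm^2; triangles below this are degenerate


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    return bool(svals[1] <= tol * max(svals[0], 1.0))


class MeshFormatError(ValueError):
    """Raised for files that cannot be interpreted as a triangle mesh."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-posed (collinear points...)."""


@dataclass
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm and ``triangles`` (m, 3) indices.

    Degenerate (zero-area) triangles are dropped at construction; the surface
    may be open, i.e. boundary edges are allowed.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise MeshFormatError("triangle indices out of range")
            areas = _triangle_areas(self.vertices, self.triangles)
            self.triangles = self.triangles[areas > _AREA_TOL]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles.copy(), self.subject_id)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    def transformed(self, transform: "RigidTransform") -> "SurfaceMesh":
        return SurfaceMesh(transform.apply(self.vertices), self.triangles.copy(), self.subject_id)

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass
class LandmarkSet:
    """The four manual landmarks: both eyes, nose tip and lip midpoint (mm)."""

    left_eye: np.ndarray
    right_eye: np.ndarray
    nose: np.ndarray
    lip_midpoint: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if _collinear(self.as_array()):
            raise DegenerateGeometryError("landmarks are collinear")

    def as_array(self) -> np.ndarray:
        return np.vstack([getattr(self, name) for name in LANDMARK_NAMES])

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        pts = transform.apply(self.as_array())
        return LandmarkSet(*pts)


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` with ``det(R) = +1``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class CuttingPlane:
    """Half-space + normal-orientation filter used to crop the face patch.

    Triangles survive the cut only if their centroid lies on the positive side
    of the plane and their outward normal is within ``normal_angle_limit``
    degrees of ``unit_normal``.
    """

    point: np.ndarray
    unit_normal: np.ndarray
    normal_angle_limit: float = 90.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        normal = np.asarray(self.unit_normal, dtype=float).reshape(3)
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        self.unit_normal = normal / norm
        if not 0 < self.normal_angle_limit <= 180:
            raise ValueError("normal_angle_limit must be in (0, 180] degrees")


# ---------------------------------------------------------------------------
# I/O


def read_mesh(path: str | Path, format_hint: str | None = None) -> SurfaceMesh:
    """Read a PLY / OBJ / STL / legacy-VTK triangle mesh (units assumed mm).

    Duplicate vertices within 1e-9 mm are merged; OBJ's 1-based indices become
    0-based.  Non-triangular cells raise :class:`MeshFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        vertices, triangles = _read_legacy_vtk(path)
    else:
        try:
            loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        except Exception as exc:  # trimesh raises assorted types for bad files
            raise MeshFormatError(f"cannot read {path} as {fmt}: {exc}") from exc
        if not isinstance(loaded, trimesh.Trimesh):
            raise MeshFormatError(f"{path} does not contain a triangle mesh")
        vertices = np.asarray(loaded.vertices, dtype=float)
        triangles = np.asarray(loaded.faces, dtype=np.int64)
    vertices, triangles = _merge_duplicate_vertices(vertices, triangles)
    return SurfaceMesh(vertices, triangles, subject_id=path.stem)


def write_mesh(mesh: SurfaceMesh, path: str | Path, format_hint: str | None = None) -> None:
    """Write a mesh; ASCII PLY is the canonical output format."""
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        _write_legacy_vtk(mesh, path)
        return
    if fmt == "ply":
        path.write_bytes(
            trimesh.exchange.ply.export_ply(mesh.to_trimesh(), encoding="ascii")
        )
        return
    mesh.to_trimesh().export(str(path), file_type=fmt)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a ``name,x,y,z`` delimited text file with exactly the 4 landmark names."""
    found: dict[str, np.ndarray] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.replace("\t", ",").split(",")]
        if parts[0].lower() in ("name", "landmark"):
            continue
        if len(parts) != 4:
            raise MeshFormatError(f"bad landmark line: {line!r}")
        found[parts[0]] = np.array([float(v) for v in parts[1:]])
    missing = set(LANDMARK_NAMES) - set(found)
    if missing:
        raise MeshFormatError(f"landmark file {path} missing: {sorted(missing)}")
    return LandmarkSet(**{name: found[name] for name in LANDMARK_NAMES})


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    lines = ["name,x,y,z"]
    for name in LANDMARK_NAMES:
        p = getattr(landmarks, name)
        lines.append(f"{name},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_legacy_vtk(path: Path) -> tuple[np.ndarray, np.ndarray]:
    # Minimal ASCII legacy VTK POLYDATA reader (POINTS + POLYGONS sections).
    tokens = path.read_text().split()
    upper = [t.upper() for t in tokens]
    if "POLYDATA" not in upper:
        raise MeshFormatError(f"{path}: not a legacy VTK POLYDATA file")
    try:
        i = upper.index("POINTS")
        n_pts = int(tokens[i + 1])
        coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float)
        vertices = coords.reshape(n_pts, 3)
        j = upper.index("POLYGONS")
        n_cells = int(tokens[j + 1])
        pos = j + 3
        faces = []
        for _ in range(n_cells):
            k = int(tokens[pos])
            if k != 3:
                raise MeshFormatError(f"{path}: non-triangular cell with {k} vertices")
            faces.append([int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])])
            pos += k + 1
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path}: malformed legacy VTK file: {exc}") from exc
    return vertices, np.array(faces, dtype=np.int64)


def _write_legacy_vtk(mesh: SurfaceMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "fetalmorph surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} float",
    ]
    lines += [f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}")
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def _merge_duplicate_vertices(
    vertices: np.ndarray, triangles: np.ndarray, tol: float = _MERGE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    if len(vertices) == 0:
        return vertices, triangles
    rounded = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(rounded, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse][triangles]


def default_cutting_plane(
    landmarks: LandmarkSet, depth_offset_mm: float = 5.0, normal_angle_limit: float = 120.0
) -> CuttingPlane:
    """Face-cropping plane derived from the landmarks.

    The plane passes through the ear-line proxy — the eye midpoint pushed
    ``depth_offset_mm`` against the facing direction — and faces the same way
    as the face (the normal points from the eye midpoint towards the nose tip
    projected out of the eye-mouth plane).  Triangles behind the plane or
    looking away by more than ``normal_angle_limit`` degrees are cut.
    """
    eyes_mid = 0.5 * (landmarks.left_eye + landmarks.right_eye)
    across = landmarks.right_eye - landmarks.left_eye
    down = landmarks.lip_midpoint - eyes_mid
    facing = np.cross(down, across)  # out of the face for a y-up, +z-facing frame
    norm = np.linalg.norm(facing)
    if norm == 0:
        raise DegenerateGeometryError("landmarks do not define a facing direction")
    facing = facing / norm
    if np.dot(landmarks.nose - eyes_mid, facing) < 0:
        facing = -facing
    return CuttingPlane(
        point=eyes_mid - depth_offset_mm * facing,
        unit_normal=facing,
        normal_angle_limit=normal_angle_limit,
    )


# ---------------------------------------------------------------------------
# Alignment


def landmark_align(landmarks: LandmarkSet, reference_landmarks: LandmarkSet) -> RigidTransform:
    """Least-squares rigid (no scaling) Procrustes fit of the 4 landmark pairs.

    Returns the transform that carries ``landmarks`` onto
    ``reference_landmarks`` with minimal sum of squared distances.
    """
    src = landmarks.as_array()
    dst = reference_landmarks.as_array()
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst_c, src_c)
    R = rot.as_matrix()
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def icp_align(
    source: SurfaceMesh,
    target: SurfaceMesh,
    max_iter: int = 50,
    tol: float = 1e-6,
    initial: RigidTransform | None = None,
) -> RigidTransform:
    """Point-to-point ICP of ``source`` vertices onto ``target`` vertices.

    ``initial`` is normally the landmark-based transform.  Iterations stop when
    the mean nearest-neighbour distance improves by less than ``tol`` (mm) or
    after ``max_iter`` steps; the best transform seen is returned, so the mean
    distance is non-increasing over accepted iterations.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("ICP requires non-empty meshes")
    transform = initial or RigidTransform.identity()
    if max_iter == 0:
        return transform
    tree = cKDTree(target.vertices)
    moved = transform.apply(source.vertices)
    best = transform
    best_err = tree.query(moved)[0].mean()
    for _ in range(max_iter):
        dists, idx = tree.query(moved)
        step = _kabsch(moved, target.vertices[idx])
        moved = step.apply(moved)
        transform = step.compose(transform)
        err = tree.query(moved)[0].mean()
        if err < best_err:
            best, improvement = transform, best_err - err
            best_err = err
            if improvement < tol:
                break
        else:
            break
    return best


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst_c, src_c)
    R = rot.as_matrix()
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# Geometry


def cell_geometry(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triangle centroid, outward unit normal (CCW winding) and area."""
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    centers = (a + b + c) / 3.0
    cross = np.cross(b - a, c - a)
    double_area = np.linalg.norm(cross, axis=1)
    areas = 0.5 * double_area
    normals = cross / np.where(double_area > 0, double_area, 1.0)[:, None]
    return centers, normals, areas


def closest_point_on_surface(
    mesh: SurfaceMesh, points: np.ndarray, chunk: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point on the triangulated surface for each query point.

    Vectorised point-triangle projection evaluated against every triangle in
    chunks of query points; returns (closest points, distances).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    V, F = mesh.vertices, mesh.triangles
    a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    closest = np.empty_like(points)
    dists = np.empty(len(points))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        cand = _closest_on_triangles(p[:, None, :], a[None], b[None], c[None])
        d2 = np.sum((cand - p[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        closest[start : start + chunk] = cand[rows, best]
        dists[start : start + chunk] = np.sqrt(d2[rows, best])
    return closest, dists


def _closest_on_triangles(p, a, b, c):
    """Closest point on triangle (a, b, c) to p; all inputs broadcastable (..., 3)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_edge_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_edge_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default
    # edge BC region
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(cond_bc[..., None], b + w_edge_bc[..., None] * (c - b), out)
    # edge AC region
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + w_edge_ac[..., None] * ac, out)
    # edge AB region
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + v_edge_ab[..., None] * ab, out)
    # vertex regions
    cond_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(cond_c[..., None], c, out)
    cond_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(cond_b[..., None], b, out)
    cond_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(cond_a[..., None], a, out)
    return out


def _triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    cross = np.cross(vertices[triangles[:, 1]] - a, vertices[triangles[:, 2]] - a)
    return 0.5 * np.linalg.norm(cross, axis=1)


def cut_mesh(mesh: SurfaceMesh, plane: CuttingPlane) -> SurfaceMesh:
    """Crop to triangles on the positive side of ``plane`` with compatible normals.

    A triangle is removed if its centroid is on the negative side of the plane
    or if its outward normal deviates from the plane normal by more than
    ``plane.normal_angle_limit`` degrees.  Only the largest connected component
    of the surviving triangles is kept; no new geometry is created.
    """
    centers, normals, _ = cell_geometry(mesh)
    side = (centers - plane.point) @ plane.unit_normal >= 0
    cosine = normals @ plane.unit_normal
    cos_limit = np.cos(np.deg2rad(plane.normal_angle_limit))
    keep = side & (cosine >= cos_limit - 1e-12)
    if not keep.any():
        raise DegenerateGeometryError("cutting plane removed every triangle")
    faces = mesh.triangles[keep]
    faces = faces[_largest_component(faces)]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces], mesh.subject_id)


def _largest_component(faces: np.ndarray) -> np.ndarray:
    """Boolean mask of faces in the largest edge-connected component."""
    n = len(faces)
    if n <= 1:
        return np.ones(n, dtype=bool)
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    face_ids = np.tile(np.arange(n), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, face_ids = edges[order], face_ids[order]
    same = (np.diff(edges, axis=0) == 0).all(axis=1)
    rows = face_ids[:-1][same]
    cols = face_ids[1:][same]
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp == 1:
        return np.ones(n, dtype=bool)
    largest = np.bincount(labels).argmax()
    return labels == largest


# ---------------------------------------------------------------------------
# Isotropic remeshing


def remesh_isotropic(
    mesh: SurfaceMesh, target_edge_mm: float, n_iterations: int = 5
) -> SurfaceMesh:
    """Edge-based isotropic remeshing towards a uniform edge length.

    Iterates long-edge splits, short-edge collapses, valence-equalising flips
    and tangential Laplacian smoothing with back-projection onto the input
    surface.  Boundary vertices stay on the boundary curve.  The output median
    edge length is within 25% of ``target_edge_mm`` for reasonable inputs.
    """
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")
    _check_manifold(mesh)
    if mesh.n_triangles <= 1:
        warnings.warn("remesh_isotropic: input has <= 1 triangle, returned unchanged")
        return mesh.copy()
    reference = mesh
    V = mesh.vertices.copy()
    F = mesh.triangles.copy()
    high = 4.0 / 3.0 * target_edge_mm
    low = 4.0 / 5.0 * target_edge_mm
    for _ in range(n_iterations):
        V, F = _split_long_edges(V, F, high)
        V, F = _collapse_short_edges(V, F, low, high)
        F = _flip_edges(V, F)
        V = _tangential_smooth(V, F, reference)
    out = SurfaceMesh(V, F, mesh.subject_id)
    v, f = _merge_duplicate_vertices(out.vertices, out.triangles)
    return SurfaceMesh(*_drop_unused_vertices(v, f), mesh.subject_id)


def _check_manifold(mesh: SurfaceMesh) -> None:
    edges = np.sort(
        np.concatenate(
            [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]], mesh.triangles[:, [2, 0]]]
        ),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bad = uniq[counts > 2]
    if len(bad):
        raise MeshFormatError(f"non-manifold edges (shared by >2 faces): {bad.tolist()[:10]}")


def _mesh_edges(F: np.ndarray) -> np.ndarray:
    edges = np.sort(np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    return np.unique(edges, axis=0)


def _boundary_vertices(F: np.ndarray) -> np.ndarray:
    edges = np.sort(np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def _split_long_edges(V: np.ndarray, F: np.ndarray, high: float) -> tuple[np.ndarray, np.ndarray]:
    edges = _mesh_edges(F)
    lengths = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
    to_split = edges[lengths > high]
    if len(to_split) == 0:
        return V, F
    midpoint_index: dict[tuple[int, int], int] = {}
    new_vertices = [V]
    next_id = len(V)
    for a, b in to_split:
        midpoint_index[(a, b)] = next_id
        new_vertices.append(0.5 * (V[a] + V[b]))
        next_id += 1
    V = np.vstack([new_vertices[0], np.array(new_vertices[1:])]) if len(new_vertices) > 1 else V

    def mid(a: int, b: int) -> int | None:
        return midpoint_index.get((a, b) if a < b else (b, a))

    new_faces: list[list[int]] = []
    for tri in F:
        i, j, k = (int(x) for x in tri)
        mij, mjk, mki = mid(i, j), mid(j, k), mid(k, i)
        n_split = sum(m is not None for m in (mij, mjk, mki))
        if n_split == 0:
            new_faces.append([i, j, k])
        elif n_split == 3:
            new_faces += [[i, mij, mki], [mij, j, mjk], [mki, mjk, k], [mij, mjk, mki]]
        elif n_split == 1:
            if mij is not None:
                new_faces += [[i, mij, k], [mij, j, k]]
            elif mjk is not None:
                new_faces += [[j, mjk, i], [mjk, k, i]]
            else:
                new_faces += [[k, mki, j], [mki, i, j]]
        else:  # two split edges: rotate so the unsplit edge is (i, j)
            if mij is None:
                pass
            elif mjk is None:
                i, j, k = j, k, i
                mjk, mki = mki, mij
            else:
                i, j, k = k, i, j
                mjk, mki = mij, mjk
            # now edges (j,k) and (k,i) are split at mjk, mki
            new_faces += [[k, mki, mjk], [i, mjk, mki], [i, j, mjk]]
    return V, np.array(new_faces, dtype=np.int64)


def _collapse_short_edges(
    V: np.ndarray, F: np.ndarray, low: float, high: float, max_sub_passes: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    # each greedy sub-pass collapses an independent set of short edges;
    # repeat until no short edge can be collapsed
    for _ in range(max_sub_passes):
        V, F, changed = _collapse_pass(V, F, low, high)
        if not changed:
            break
    return V, F


def _collapse_pass(
    V: np.ndarray, F: np.ndarray, low: float, high: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    edges = _mesh_edges(F)
    lengths = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
    order = np.argsort(lengths)
    candidates = edges[order][lengths[order] < low]
    if len(candidates) == 0:
        return V, F, False
    boundary = set(_boundary_vertices(F).tolist())
    boundary_edges = _boundary_edge_set(F)
    neighbors = _vertex_neighbors(F, len(V))
    positions = V.copy()
    merged = np.arange(len(V))
    touched: set[int] = set()
    for a, b in candidates:
        a, b = int(a), int(b)
        if a in touched or b in touched:
            continue
        a_bnd, b_bnd = a in boundary, b in boundary
        if a_bnd and b_bnd and (a, b) not in boundary_edges and (b, a) not in boundary_edges:
            continue  # would pinch two distinct boundary pieces together
        # link condition: common neighbours must be exactly the edge's opposite vertices
        common = neighbors[a] & neighbors[b]
        if len(common) > 2:
            continue
        if a_bnd and b_bnd:
            new_pos = 0.5 * (positions[a] + positions[b])
        elif a_bnd:
            new_pos = positions[a]
        elif b_bnd:
            new_pos = positions[b]
        else:
            new_pos = 0.5 * (positions[a] + positions[b])
        ring = (neighbors[a] | neighbors[b]) - {a, b}
        if any(np.linalg.norm(new_pos - positions[v]) > high for v in ring):
            continue
        positions[a] = new_pos
        merged[b] = a
        touched.update(ring | {a, b})
    changed = bool(np.any(merged != np.arange(len(V))))
    F2 = merged[F]
    keep = (
        (F2[:, 0] != F2[:, 1]) & (F2[:, 1] != F2[:, 2]) & (F2[:, 2] != F2[:, 0])
    )
    F2 = F2[keep]
    V2, F2 = _drop_unused_vertices(positions, F2)
    return V2, F2, changed


def _boundary_edge_set(F: np.ndarray) -> set[tuple[int, int]]:
    edges = np.sort(np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return {tuple(e) for e in uniq[counts == 1]}


def _vertex_neighbors(F: np.ndarray, n: int) -> list[set[int]]:
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j, k in F:
        neighbors[i].update((j, k))
        neighbors[j].update((i, k))
        neighbors[k].update((i, j))
    return neighbors


def _flip_edges(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """One pass of valence-equalising edge flips on interior edges."""
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (i, j, k) in enumerate(F):
        for a, b in ((i, j), (j, k), (k, i)):
            key = (a, b) if a < b else (b, a)
            edge_faces.setdefault(key, []).append(fi)
    valence = np.bincount(F.ravel(), minlength=len(V))
    boundary = set(_boundary_vertices(F).tolist())
    target = np.array([4 if v in boundary else 6 for v in range(len(V))])
    F = F.copy()
    flipped_faces: set[int] = set()
    existing = set(edge_faces.keys())
    for (a, b), faces in edge_faces.items():
        if len(faces) != 2 or faces[0] in flipped_faces or faces[1] in flipped_faces:
            continue
        f0, f1 = faces
        c = [v for v in F[f0] if v not in (a, b)][0]
        d = [v for v in F[f1] if v not in (a, b)][0]
        key_cd = (c, d) if c < d else (d, c)
        if key_cd in existing:
            continue
        dev_before = sum((valence[v] - target[v]) ** 2 for v in (a, b, c, d))
        valence_after = {a: valence[a] - 1, b: valence[b] - 1, c: valence[c] + 1, d: valence[d] + 1}
        dev_after = sum((valence_after[v] - target[v]) ** 2 for v in (a, b, c, d))
        if dev_after >= dev_before:
            continue
        if not _flip_preserves_geometry(V, a, b, c, d):
            continue
        F[f0] = _oriented_face(F[f0], a, b, c, d, first=True)
        F[f1] = _oriented_face(F[f1], a, b, c, d, first=False)
        flipped_faces.update((f0, f1))
        existing.discard((a, b) if a < b else (b, a))
        existing.add(key_cd)
        for v, new_val in valence_after.items():
            valence[v] = new_val
    return F


def _oriented_face(face, a, b, c, d, first: bool):
    # replace edge (a,b) by (c,d), preserving winding of the face containing c
    face = list(face)
    idx_a, idx_b = face.index(a), face.index(b)
    if first:
        face[idx_b if (idx_a + 1) % 3 == idx_b else idx_a] = d
    else:
        face[idx_b if (idx_a + 1) % 3 == idx_b else idx_a] = c
    return face


def _flip_preserves_geometry(V, a, b, c, d) -> bool:
    # reject flips that would create a degenerate or folded pair of triangles
    def area_normal(p, q, r):
        return np.cross(V[q] - V[p], V[r] - V[p])

    n_old = area_normal(a, b, c) + area_normal(b, a, d)
    n1, n2 = area_normal(c, d, a), area_normal(d, c, b)
    if np.linalg.norm(n1) < _AREA_TOL or np.linalg.norm(n2) < _AREA_TOL:
        return False
    n_new = n1 + n2
    denom = np.linalg.norm(n_old) * np.linalg.norm(n_new)
    return denom > 0 and np.dot(n_old, n_new) / denom > 0.5


def _tangential_smooth(
    V: np.ndarray, F: np.ndarray, reference: SurfaceMesh, lam: float = 0.6
) -> np.ndarray:
    n = len(V)
    neighbors = _vertex_neighbors(F, n)
    boundary = set(_boundary_vertices(F).tolist())
    out = V.copy()
    interior = [v for v in range(n) if v not in boundary and neighbors[v]]
    if not interior:
        return out
    centroids = np.array([np.mean([V[u] for u in neighbors[v]], axis=0) for v in interior])
    out[interior] = V[interior] + lam * (centroids - V[interior])
    closest, _ = closest_point_on_surface(reference, out[interior])
    out[interior] = closest
    return out


def _drop_unused_vertices(V: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    used = np.unique(F)
    remap = np.full(len(V), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return V[used], remap[F]
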
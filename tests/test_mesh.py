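import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import trimesh

from fetalmorph.mesh import (
    CuttingPlane,
    DegenerateGeometryError,
    LandmarkSet,
    RigidTransform,
    SurfaceMesh,
    cell_geometry,
    closest_point_on_surface,
    cut_mesh,
    icp_align,
    landmark_align,
    read_landmarks,
    read_mesh,
    remesh_isotropic,
    write_landmarks,
    write_mesh,
)

SQUARE = SurfaceMesh(
    np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]),
    np.array([[0, 1, 2], [0, 2, 3]]),
)


def _landmarks(offset=np.zeros(3)):
    return LandmarkSet(
        left_eye=np.array([-11.0, 8, 20]) + offset,
        right_eye=np.array([11.0, 8, 20]) + offset,
        nose=np.array([0.0, -4, 30]) + offset,
        lip_midpoint=np.array([0.0, -16, 24]) + offset,
    )


def _icosphere(radius=1.0, subdivisions=2):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces))


# ---------------------------------------------------------------------------
# I/O


@pytest.mark.parametrize("fmt", ["ply", "obj", "stl", "vtk"])
def test_mesh_roundtrip(tmp_path, fmt):
    path = tmp_path / f"square.{fmt}"
    write_mesh(SQUARE, path)
    back = read_mesh(path)
    if fmt == "stl":  # STL stores per-facet vertices; merging restores the square
        assert back.n_triangles == 2
        assert back.n_vertices == 4
    else:
        np.testing.assert_allclose(back.vertices, SQUARE.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.triangles, SQUARE.triangles)


def test_obj_indices_are_rebased(tmp_path):
    path = tmp_path / "tri.obj"
    path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
    mesh = read_mesh(path)
    np.testing.assert_array_equal(mesh.triangles, [[0, 1, 2]])


def test_template_ply_roundtrip_count(tmp_path, template_face):
    template, _ = template_face
    path = tmp_path / "template.ply"
    write_mesh(template, path)
    assert read_mesh(path).n_vertices == template.n_vertices


def test_read_missing_file_raises():
    with pytest.raises(IOError):
        read_mesh("/nonexistent/path.ply")


def test_vtk_non_triangular_cell_names_the_cell(tmp_path):
    path = tmp_path / "quad.vtk"
    path.write_text(
        "# vtk DataFile Version 3.0\nq\nASCII\nDATASET POLYDATA\n"
        "POINTS 4 float\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n"
        "POLYGONS 1 5\n4 0 1 2 3\n"
    )
    with pytest.raises(ValueError, match="non-triangular"):
        read_mesh(path)


def test_landmark_file_roundtrip(tmp_path):
    lm = _landmarks()
    path = tmp_path / "lm.csv"
    write_landmarks(lm, path)
    np.testing.assert_allclose(read_landmarks(path).as_array(), lm.as_array())


# ---------------------------------------------------------------------------
# Rigid alignment


def test_landmark_align_identity():
    lm = _landmarks()
    t = landmark_align(lm, lm)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t.translation, 0, atol=1e-9)


def test_landmark_align_recovers_exact_rigid_motion():
    lm = _landmarks()
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    shift = np.array([1.0, 2.0, 3.0])
    moved = LandmarkSet(*(lm.as_array() @ R.T + shift))
    t = landmark_align(lm, moved)
    np.testing.assert_allclose(t.rotation, R, atol=1e-9)
    np.testing.assert_allclose(t.translation, shift, atol=1e-9)


def test_landmark_align_matches_quaternion_grid_oracle():
    """Noisy fit residual agrees with a brute-force search over rotations."""
    rng = np.random.default_rng(0)
    lm = _landmarks()
    R = Rotation.from_euler("xyz", [10, -20, 35], degrees=True).as_matrix()
    target_pts = lm.as_array() @ R.T + np.array([0.5, -1.0, 2.0])
    target_pts += rng.normal(0, 0.1, target_pts.shape)
    target = LandmarkSet(*target_pts)
    t = landmark_align(lm, target)
    fitted = np.sum((t.apply(lm.as_array()) - target.as_array()) ** 2)

    # oracle: random-quaternion grid, translation optimal per rotation
    best = np.inf
    src = lm.as_array()
    src_c = src - src.mean(axis=0)
    dst_c = target.as_array() - target.as_array().mean(axis=0)
    for q in Rotation.random(20000, random_state=1):
        resid = np.sum((src_c @ q.as_matrix().T - dst_c) ** 2)
        best = min(best, resid)
    assert fitted <= best * 1.05


def test_landmark_align_idempotent():
    lm = _landmarks()
    target = _landmarks(offset=np.array([3.0, 1.0, -2.0]))
    aligned = lm.transformed(landmark_align(lm, target))
    t2 = landmark_align(aligned, target)
    np.testing.assert_allclose(t2.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t2.translation, 0, atol=1e-9)


def test_collinear_landmarks_rejected():
    with pytest.raises(DegenerateGeometryError):
        LandmarkSet(
            left_eye=[0, 0, 0], right_eye=[1, 0, 0], nose=[2, 0, 0], lip_midpoint=[3, 0, 0]
        )


def test_icp_identity_and_zero_iterations(template_face):
    mesh, _ = template_face
    t = icp_align(mesh, mesh, max_iter=20, tol=1e-8)
    np.testing.assert_allclose(t.apply(mesh.vertices), mesh.vertices, atol=1e-6)
    init = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
    assert icp_align(mesh, mesh, max_iter=0, initial=init) is init


def test_icp_recovers_small_rotation(template_face):
    mesh, lm = template_face
    R = Rotation.from_euler("y", 5, degrees=True)
    target = SurfaceMesh(mesh.vertices @ R.as_matrix().T, mesh.triangles)
    init = landmark_align(lm, LandmarkSet(*(lm.as_array() @ R.as_matrix().T)))
    t = icp_align(mesh, target, max_iter=30, initial=init)
    err = Rotation.from_matrix(t.rotation.T @ R.as_matrix()).magnitude()
    assert np.rad2deg(err) < 0.1


# ---------------------------------------------------------------------------
# Cutting and cell geometry


def test_cut_plane_below_keeps_everything():
    plane = CuttingPlane(point=[0, 0, -100], unit_normal=[0, 0, 1], normal_angle_limit=180)
    out = cut_mesh(SQUARE, plane)
    assert out.n_triangles == SQUARE.n_triangles


def test_cut_sphere_at_equator():
    sphere = _icosphere(radius=1.0)
    plane = CuttingPlane(point=[0, 0, 0], unit_normal=[0, 0, 1], normal_angle_limit=90)
    out = cut_mesh(sphere, plane)
    centers, normals, _ = cell_geometry(out)
    assert np.all(centers[:, 2] >= -1e-12)
    assert np.all(normals[:, 2] >= -1e-12)


def test_cut_plane_above_mesh_errors():
    plane = CuttingPlane(point=[0, 0, 100], unit_normal=[0, 0, 1])
    with pytest.raises(DegenerateGeometryError):
        cut_mesh(SQUARE, plane)


def test_cut_returns_subset_of_input_triangles(template_face):
    mesh, _ = template_face
    plane = CuttingPlane(point=mesh.vertices.mean(axis=0), unit_normal=[0, 1, 0],
                         normal_angle_limit=180)
    out = cut_mesh(mesh, plane)
    in_tris = {tuple(sorted(map(tuple, mesh.vertices[t]))) for t in mesh.triangles}
    out_tris = {tuple(sorted(map(tuple, out.vertices[t]))) for t in out.triangles}
    assert out_tris <= in_tris


def test_default_cutting_plane_keeps_face_patch(template_face):
    from fetalmorph.mesh import default_cutting_plane

    mesh, lm = template_face
    plane = default_cutting_plane(lm)
    assert np.linalg.norm(plane.unit_normal) == pytest.approx(1.0)
    # normal faces the same way as the face (towards +z in the canonical frame)
    assert plane.unit_normal[2] > 0.9
    out = cut_mesh(mesh, plane)
    assert 0 < out.n_triangles <= mesh.n_triangles
    # the landmarks' immediate surroundings survive the crop
    for name in ("nose", "lip_midpoint"):
        p = getattr(lm, name)
        assert np.linalg.norm(out.vertices - p, axis=1).min() < 3.0


def test_cell_geometry_unit_triangle_and_winding():
    tri = SurfaceMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]]))
    centers, normals, areas = cell_geometry(tri)
    np.testing.assert_allclose(areas, [0.5])
    np.testing.assert_allclose(normals, [[0, 0, 1]])
    np.testing.assert_allclose(centers, [[1 / 3, 1 / 3, 0]])
    flipped = SurfaceMesh(tri.vertices, np.array([[0, 2, 1]]))
    np.testing.assert_allclose(cell_geometry(flipped)[1], [[0, 0, -1]])


def test_sphere_area_from_cells():
    sphere = _icosphere(radius=2.0, subdivisions=3)
    _, _, areas = cell_geometry(sphere)
    assert abs(areas.sum() - 16 * np.pi) < 0.02 * 16 * np.pi


def test_cells_invariant_under_rigid_motion(template_face):
    mesh, _ = template_face
    t = RigidTransform(
        Rotation.from_euler("xyz", [15, -40, 60], degrees=True).as_matrix(),
        np.array([5.0, -3.0, 7.0]),
    )
    moved = mesh.transformed(t)
    c0, _, a0 = cell_geometry(mesh)
    c1, _, a1 = cell_geometry(moved)
    np.testing.assert_allclose(a1, a0, rtol=1e-9)
    np.testing.assert_allclose(c1, t.apply(c0), atol=1e-9)


def test_rigid_transform_compose_inverse():
    rng = np.random.default_rng(4)
    t1 = RigidTransform(Rotation.random(random_state=1).as_matrix(), rng.normal(size=3))
    t2 = RigidTransform(Rotation.random(random_state=2).as_matrix(), rng.normal(size=3))
    pts = rng.normal(size=(10, 3))
    np.testing.assert_allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-12)
    np.testing.assert_allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-12)


def test_closest_point_on_surface_exactness():
    rng = np.random.default_rng(1)
    sphere = _icosphere(radius=3.0, subdivisions=2)
    pts = rng.normal(size=(50, 3)) * 5
    closest, dist = closest_point_on_surface(sphere, pts)
    np.testing.assert_allclose(np.linalg.norm(closest - pts, axis=1), dist, atol=1e-12)
    # brute-force check on a few points
    from fetalmorph.mesh import _closest_on_triangles

    V, F = sphere.vertices, sphere.triangles
    for i in range(5):
        cand = _closest_on_triangles(
            pts[i][None, None], V[F[:, 0]][None], V[F[:, 1]][None], V[F[:, 2]][None]
        )
        d_all = np.linalg.norm(cand[0] - pts[i], axis=-1)
        assert abs(dist[i] - d_all.min()) < 1e-12


# ---------------------------------------------------------------------------
# Remeshing


def _edge_lengths(mesh: SurfaceMesh) -> np.ndarray:
    from fetalmorph.mesh import _mesh_edges

    e = _mesh_edges(mesh.triangles)
    return np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)


def test_remesh_at_target_density_is_stable(template_face):
    """Remeshing a mesh already at the target density barely changes it."""
    mesh, _ = template_face
    target = float(np.median(_edge_lengths(mesh)))
    at_density = remesh_isotropic(mesh, target, n_iterations=3)
    out = remesh_isotropic(at_density, target, n_iterations=3)
    assert abs(out.n_triangles - at_density.n_triangles) < 0.1 * at_density.n_triangles
    assert abs(np.median(_edge_lengths(out)) - target) < 0.25 * target


def test_remesh_refines_coarse_sphere():
    sphere = _icosphere(radius=10.0, subdivisions=1)
    target = 0.2 * float(np.mean(_edge_lengths(sphere)))
    out = remesh_isotropic(sphere, target, n_iterations=4)
    assert out.n_triangles > sphere.n_triangles
    assert abs(np.median(_edge_lengths(out)) - target) < 0.25 * target
    # Hausdorff-style distance to input below the target edge length
    _, d1 = closest_point_on_surface(sphere, out.vertices)
    _, d2 = closest_point_on_surface(out, sphere.vertices)
    assert max(d1.max(), d2.max()) < target


def test_remesh_coarsens(template_face):
    mesh, _ = template_face
    target = 3.0 * float(np.median(_edge_lengths(mesh)))
    out = remesh_isotropic(mesh, target, n_iterations=5)
    assert out.n_triangles < mesh.n_triangles
    assert abs(np.median(_edge_lengths(out)) - target) < 0.25 * target


def test_remesh_single_triangle_warns():
    tri = SurfaceMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]]))
    with pytest.warns(UserWarning):
        out = remesh_isotropic(tri, 0.5)
    assert out.n_triangles == 1


def test_remesh_rejects_non_manifold():
    V = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0.5]])
    F = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) in three faces
    with pytest.raises(ValueError, match="non-manifold"):
        remesh_isotropic(SurfaceMesh(V, F), 0.5)


def test_remesh_keeps_boundary_on_boundary():
    mesh = SQUARE
    out = remesh_isotropic(mesh, 0.3, n_iterations=3)
    from fetalmorph.mesh import _boundary_vertices

    bverts = out.vertices[_boundary_vertices(out.triangles)]
    # boundary of the unit square: at least one coordinate at 0 or 1
    on_edge = (
        np.isclose(bverts[:, 0], 0) | np.isclose(bverts[:, 0], 1)
        | np.isclose(bverts[:, 1], 0) | np.isclose(bverts[:, 1], 1)
    )
    assert on_edge.all()
    assert np.allclose(bverts[:, 2], 0)
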
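"""Mesh I/O, ground-plane fitting, foot frame and PCA bone frames."""

import numpy as np
import pytest

from pedarch.errors import (
    DegeneracyWarning,
    GeometryError,
    MeshParseError,
    MeshValidationError,
    PlaneFitError,
)
from pedarch.mesh import (
    FootFrame,
    GroundPlane,
    TriangleMesh,
    _m2_head_plantar,
    compute_foot_frame,
    fit_ground_plane,
    pca_bone_frame,
    read_stl,
    realign,
    write_stl,
)
from pedarch.synthetic import make_bone_mesh, rotation_from_angles

TETRA_VERTS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
TETRA_FACES = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def _ascii_stl(triangles):
    lines = ["solid test"]
    for tri in triangles:
        lines.append(" facet normal 0 0 0")
        lines.append("  outer loop")
        for v in tri:
            lines.append(f"   vertex {v[0]} {v[1]} {v[2]}")
        lines.append("  endloop")
        lines.append(" endfacet")
    lines.append("endsolid test")
    return "\n".join(lines)


class TestStlIO:
    def test_ascii_tetrahedron(self, tmp_path):
        tris = [TETRA_VERTS[f] for f in TETRA_FACES]
        path = tmp_path / "m1.stl"
        path.write_text(_ascii_stl(tris))
        mesh = read_stl(path)
        assert mesh.label == "M1"
        assert len(mesh.vertices) == 4
        assert len(mesh.faces) == 4

    def test_binary_roundtrip(self, tmp_path):
        mesh = TriangleMesh(TETRA_VERTS, TETRA_FACES, "P3")
        path = tmp_path / "p3.stl"
        write_stl(mesh, path)
        back = read_stl(path)
        assert back.label == "P3"
        orig = {tuple(v) for v in mesh.vertices}
        got = {tuple(v) for v in back.vertices}
        assert got == orig

    def test_cube_with_duplicated_corners(self, tmp_path):
        # 12 facets listing each corner repeatedly; dedup must give 8
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        quads = [
            (0, 1, 3, 2), (4, 5, 7, 6), (0, 1, 5, 4),
            (2, 3, 7, 6), (0, 2, 6, 4), (1, 3, 7, 5),
        ]
        tris = []
        for a, b, c, d in quads:
            tris.append(corners[[a, b, c]])
            tris.append(corners[[a, c, d]])
        path = tmp_path / "cub.stl"
        path.write_text(_ascii_stl(tris))
        mesh = read_stl(path)
        # brute-force oracle: unique coordinate triples
        assert len({tuple(v) for v in mesh.vertices}) == 8
        assert len(mesh.vertices) == 8

    def test_malformed_stl(self, tmp_path):
        path = tmp_path / "m2.stl"
        path.write_bytes(b"solid\x00garbage not a mesh")
        with pytest.raises(MeshParseError):
            read_stl(path)

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "femur.stl"
        path.write_text(_ascii_stl([TETRA_VERTS[f] for f in TETRA_FACES]))
        with pytest.raises(MeshValidationError):
            read_stl(path)


class TestMeshValidation:
    def test_bone_needs_four_noncoplanar_vertices(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(MeshValidationError):
            TriangleMesh(flat, np.array([[0, 1, 2], [1, 2, 3]]), "M1")

    def test_face_index_out_of_range(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh(TETRA_VERTS, np.array([[0, 1, 9]]), "M1")


class TestGroundPlane:
    def _grid(self, z=0.0):
        xs, ys = np.meshgrid(np.linspace(0, 100, 5), np.linspace(0, 100, 5))
        return np.column_stack([xs.ravel(), ys.ravel(), np.full(xs.size, z)])

    def test_flat_plane(self):
        mesh = TriangleMesh(self._grid(), np.array([[0, 1, 5]]), "GROUND")
        plane = fit_ground_plane(mesh, toward=np.array([50, 50, 100.0]))
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert abs(plane.offset) < 1e-12

    def test_rotation_equivariance(self):
        R = rotation_from_angles(25.0, 40.0, 10.0)
        pts = self._grid() @ R.T
        mesh = TriangleMesh(pts, np.array([[0, 1, 5]]), "GROUND")
        plane = fit_ground_plane(mesh, toward=R @ np.array([50, 50, 100.0]))
        np.testing.assert_allclose(plane.normal, R @ np.array([0, 0, 1.0]), atol=1e-9)

    def test_noisy_plane_offset(self, rng):
        pts = self._grid(z=2.0)
        pts[:, 2] += rng.uniform(-0.01, 0.01, len(pts))
        mesh = TriangleMesh(pts, np.array([[0, 1, 5]]), "GROUND")
        plane = fit_ground_plane(mesh, toward=np.array([50, 50, 100.0]))
        assert abs(plane.offset - 2.0) <= 0.01

    def test_collinear_vertices_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        mesh = TriangleMesh(pts, np.array([[0, 1, 2]]), "GROUND")
        with pytest.raises(PlaneFitError):
            fit_ground_plane(mesh)


def _cal_mesh(plantar=(0.0, 0.0, 1.0)):
    px, py, pz = plantar
    verts = np.array(
        [[px, py, pz], [px, py, pz + 7], [px + 5, py + 3, pz + 5],
         [px - 5, py + 3, pz + 5], [px, py - 5, pz + 6]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4], [2, 3, 4]])
    return TriangleMesh(verts, faces, "CAL")


def _m2_mesh(head_low=(120.0, 0.0, 2.0)):
    """Elongated vertex cloud along x whose distal-region lowest vertex is
    ``head_low``; a lower vertex sits proximally to exercise the
    head-region selection."""
    xs = np.arange(95.0, 126.0, 5.0)
    verts = []
    for x in xs:
        for dy, dz in [(3, 8), (-3, 8), (0, 11), (0, 6)]:
            verts.append((x, dy, dz))
    verts.append((100.0, 0.0, 1.5))  # globally lowest, but proximal
    verts.append(head_low)  # lowest within the distal head region
    verts = np.array(verts)
    faces = np.array([[0, 1, 2], [0, 2, 3], [1, 2, 3]])
    return TriangleMesh(verts, faces, "M2")


class TestFootFrame:
    def test_axes_from_plantar_points(self):
        ground = GroundPlane(np.array([0, 0, 1.0]), 0.0)
        frame = compute_foot_frame(_cal_mesh(), _m2_mesh((120.0, 0.0, 2.0)), ground)
        np.testing.assert_allclose(frame.ap_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.vert_axis, [0, 0, 1], atol=1e-12)

    def test_oblique_ap_axis(self):
        ground = GroundPlane(np.array([0, 0, 1.0]), 0.0)
        frame = compute_foot_frame(_cal_mesh(), _m2_mesh((120.0, 5.0, 2.0)), ground)
        expected = np.array([120.0, 5.0, 0.0])
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(frame.ap_axis, expected, atol=1e-9)
        assert frame.ap_axis[0] == pytest.approx(0.99914, abs=1e-5)
        assert frame.ap_axis[1] == pytest.approx(0.04163, abs=1e-5)

    def test_orthonormal_and_right_handed(self):
        ground = GroundPlane(np.array([0, 0, 1.0]), 0.0)
        frame = compute_foot_frame(_cal_mesh(), _m2_mesh((118.0, -7.0, 3.0)), ground)
        R = frame.rotation
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_plantar_projections_rejected(self):
        ground = GroundPlane(np.array([0, 0, 1.0]), 0.0)
        m2 = _m2_mesh((120.0, 0.0, 2.0))
        p = _m2_head_plantar(m2, ground, np.array([1.0, 0, 0]))
        # calcaneus body posterior, but its plantar apex directly below the
        # M2 head's plantar point
        verts = np.array(
            [[p[0], p[1], 1.0], [10, 0, 40], [15, 8, 35], [15, -8, 35], [5, 0, 30.0]]
        )
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4], [2, 3, 4]])
        cal = TriangleMesh(verts, faces, "CAL")
        with pytest.raises(GeometryError):
            compute_foot_frame(cal, m2, ground)


class TestRealign:
    def test_identity_frame_is_noop(self):
        mesh = _cal_mesh()
        out = realign([mesh], FootFrame.identity())[0]
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_quarter_turn_about_vertical(self):
        frame = FootFrame(
            np.zeros(3), np.array([0, 1, 0.0]), np.array([-1, 0, 0.0]),
            np.array([0, 0, 1.0]),
        )
        mesh = _cal_mesh()
        out = realign([mesh], frame)[0]
        np.testing.assert_allclose(out.vertices[:, 0], mesh.vertices[:, 1], atol=1e-12)
        np.testing.assert_allclose(out.vertices[:, 1], -mesh.vertices[:, 0], atol=1e-12)

    def test_distances_preserved(self, rng):
        frame = FootFrame(
            rng.normal(size=3),
            np.array([0, 1, 0.0]),
            np.array([-1, 0, 0.0]),
            np.array([0, 0, 1.0]),
        )
        mesh = _cal_mesh()
        out = realign([mesh], frame)[0]
        d0 = np.linalg.norm(mesh.vertices[:, None] - mesh.vertices[None], axis=-1)
        d1 = np.linalg.norm(out.vertices[:, None] - out.vertices[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestPcaBoneFrame:
    def test_axis_aligned_ellipsoid(self):
        mesh, _ = make_bone_mesh((30, 10, 5), np.eye(3), (0, 0, 20), label="M1")
        bf = pca_bone_frame(mesh)
        np.testing.assert_allclose(np.abs(bf.longitudinal_axis), [1, 0, 0], atol=1e-6)
        assert bf.longitudinal_axis[0] > 0  # anterior-positive sign rule
        assert bf.variances[0] > bf.variances[1] > bf.variances[2] > 0

    def test_rotated_ellipsoid_recovers_planted_axis(self):
        R = rotation_from_angles(30.0, 0.0)
        mesh, truth = make_bone_mesh((30, 10, 5), R, (0, 0, 40), label="M1")
        bf = pca_bone_frame(mesh)
        planted = truth["axes"][:, 0]
        angle = np.degrees(
            np.arccos(np.clip(abs(bf.longitudinal_axis @ planted), -1, 1))
        )
        assert angle < 1e-3

    def test_near_spherical_bone_warns(self):
        mesh, _ = make_bone_mesh((10, 9.9, 5), np.eye(3), (0, 0, 20), label="NAV")
        with pytest.warns(DegeneracyWarning):
            bf = pca_bone_frame(mesh)
        assert bf.degenerate

    def test_right_handed_triad(self):
        R = rotation_from_angles(-20.0, 5.0, 12.0)
        mesh, _ = make_bone_mesh((34, 8.5, 7.5), R, (100, 10, 15), label="M2")
        bf = pca_bone_frame(mesh)
        np.testing.assert_allclose(
            np.cross(bf.longitudinal_axis, bf.ml_axis), bf.dp_axis, atol=1e-9
        )


class TestRigidInvariance:
    def test_downstream_variables_invariant_to_scanner_pose(self, synthetic_foot):
        """One rigid transform applied to all meshes including the ground
        leaves every angle and height unchanged."""
        from pedarch.pipeline import process_foot_meshes
        from pedarch.synthetic import _random_rotation

        base, _ = process_foot_meshes(synthetic_foot.meshes)
        rng = np.random.default_rng(4)
        R = _random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        moved = {k: m.transformed(R, t) for k, m in synthetic_foot.meshes.items()}
        again, _ = process_foot_meshes(moved)
        np.testing.assert_allclose(base.values, again.values, atol=1e-6)
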
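"""Rigid registration, sphere fitting, frames, landmark I/O."""

import numpy as np
import pytest
import trimesh
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from limbssm.errors import DegenerateGeometryError, InputError, MissingLandmarkError
from limbssm.geometry import (Frame, Landmark, LandmarkSet, RigidTransform,
                              build_segment_frame, fit_sphere, icp_register,
                              new_mesh, rigid_align, surface_rmse)
from limbssm.proximity import SurfaceQuery


def random_rigid(rng) -> RigidTransform:
    return RigidTransform(Rotation.from_rotvec(rng.normal(0, 1, 3)).as_matrix(),
                          rng.normal(0, 50, 3))


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(InputError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse(self, rng):
        T = random_rigid(rng)
        pts = rng.normal(0, 10, (5, 3))
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-9)


class TestRigidAlign:
    def test_identity(self, rng):
        pts = rng.normal(0, 10, (8, 3))
        T = rigid_align(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0, atol=1e-9)

    def test_exact_rigid_motion_recovered(self, rng):
        pts = rng.normal(0, 10, (6, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        T = rigid_align(pts, pts @ R.T + t)
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)
        np.testing.assert_allclose(T.translation, t, atol=1e-8)
        assert np.linalg.norm(T.apply(pts) - (pts @ R.T + t)) < 1e-9

    def test_noisy_fit_matches_nonlinear_least_squares(self, rng):
        """Closed-form solution agrees with brute-force nonlinear minimisation."""
        src = rng.normal(0, 30, (10, 3))
        truth = random_rigid(rng)
        dst = truth.apply(src) + rng.normal(0, 0.1, (10, 3))
        T = rigid_align(src, dst)
        ang = Rotation.from_matrix(T.rotation.T @ truth.rotation).magnitude()
        assert np.degrees(ang) < 1.0

        def resid(x):
            M = Rotation.from_rotvec(x[:3]).as_matrix()
            return (src @ M.T + x[3:] - dst).ravel()

        best = np.inf
        for k in range(8):
            r = np.random.default_rng(k)
            sol = least_squares(resid, np.concatenate([r.normal(0, 1, 3),
                                                       r.normal(0, 20, 3)]))
            best = min(best, 2 * sol.cost)
        ours = np.sum((T.apply(src) - dst) ** 2)
        assert ours <= best + 1e-8

    def test_optimal_among_random_transforms(self, rng):
        src = rng.normal(0, 20, (12, 3))
        dst = random_rigid(rng).apply(src) + rng.normal(0, 0.5, (12, 3))
        ours = np.sum((rigid_align(src, dst).apply(src) - dst) ** 2)
        for _ in range(1000):
            other = np.sum((random_rigid(rng).apply(src) - dst) ** 2)
            assert ours <= other + 1e-9

    def test_collinear_raises(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            rigid_align(pts, pts)


@pytest.fixture(scope="module")
def ellipsoid():
    m = trimesh.creation.icosphere(subdivisions=2)
    v = np.asarray(m.vertices) * np.array([30.0, 50.0, 20.0])
    return new_mesh(v, np.asarray(m.faces))


class TestICP:
    def test_identical_meshes(self, ellipsoid):
        _, rmse = icp_register(ellipsoid, ellipsoid)
        assert rmse < 1e-9

    def test_small_rigid_motion_recovered(self, ellipsoid, rng):
        T = RigidTransform(Rotation.from_euler("xyz", [5, -3, 4], degrees=True).as_matrix(),
                           np.array([5.0, -2.0, 3.0]))
        moved = new_mesh(T.apply(ellipsoid.vertices), ellipsoid.faces)
        _, rmse = icp_register(moved, ellipsoid, tolerance=1e-12)
        assert rmse < 1e-6

    def test_scaled_mesh_vs_rotation_grid_oracle(self, ellipsoid, rng):
        """ICP residual on a 1.05-scaled copy is at least as good as the best
        of many random-rotation + Kabsch alignments."""
        scaled = new_mesh(np.asarray(ellipsoid.vertices) * 1.05, ellipsoid.faces)
        _, rmse = icp_register(scaled, ellipsoid, tolerance=1e-10)
        assert rmse > 0
        query = SurfaceQuery(ellipsoid)
        src = np.asarray(scaled.vertices)
        best = np.inf
        for _ in range(200):
            R = Rotation.from_rotvec(rng.normal(0, 2, 3)).as_matrix()
            rotated = src @ R.T
            closest, _ = query.closest(rotated)
            T = rigid_align(src, closest)
            _, d = query.closest(T.apply(src))
            best = min(best, float(np.sqrt(np.mean(d ** 2))))
        assert rmse <= best + 1e-9

    def test_empty_mesh_raises(self, ellipsoid):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3)))
        with pytest.raises(InputError):
            icp_register(empty, ellipsoid)


class TestSurfaceRMSE:
    def test_identity_zero(self, ellipsoid):
        assert surface_rmse(ellipsoid, ellipsoid) < 1e-9

    def test_offset_sphere_one_mm(self):
        s = trimesh.creation.icosphere(subdivisions=3)
        inner = new_mesh(np.asarray(s.vertices) * 30.0, np.asarray(s.faces))
        outer = new_mesh(np.asarray(s.vertices) * 31.0, np.asarray(s.faces))
        # tolerance covers facet sag: chords of the inner icosphere lie up to
        # r(1 - cos(half edge angle)) ~ 0.08 mm inside the true sphere
        assert abs(surface_rmse(outer, inner) - 1.0) < 0.1

    def test_rigid_invariance(self, ellipsoid, rng):
        bumpy = new_mesh(np.asarray(ellipsoid.vertices) * [1.02, 0.99, 1.01],
                         ellipsoid.faces)
        base = surface_rmse(bumpy, ellipsoid)
        T = random_rigid(rng)
        moved = new_mesh(T.apply(bumpy.vertices), bumpy.faces)
        assert abs(surface_rmse(moved, ellipsoid) - base) < 1e-6


class TestFitSphere:
    def test_unit_sphere_from_five_points(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]],
                       dtype=float)
        c, r = fit_sphere(pts)
        np.testing.assert_allclose(c, 0, atol=1e-9)
        assert abs(r - 1.0) < 1e-9

    def test_noiseless_consistency(self, rng):
        centre = np.array([10.0, -5.0, 3.0])
        radius = 21.1
        u = rng.normal(size=(50, 3))
        pts = centre + radius * u / np.linalg.norm(u, axis=1, keepdims=True)
        c, r = fit_sphere(pts)
        np.testing.assert_allclose(c, centre, atol=1e-9)
        assert abs(r - radius) < 1e-9

    def test_noisy_matches_geometric_refit(self, rng):
        centre = np.array([2.0, 1.0, -4.0])
        u = rng.normal(size=(200, 3))
        pts = centre + 25.0 * u / np.linalg.norm(u, axis=1, keepdims=True)
        pts += rng.normal(0, 0.5, pts.shape)
        c, r = fit_sphere(pts)

        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        sol = least_squares(resid, np.concatenate([c, [r]])).x
        assert np.linalg.norm(c - sol[:3]) < 0.05
        assert abs(r - sol[3]) < 0.05

    def test_coplanar_raises(self, rng):
        pts = rng.normal(0, 5, (20, 3))
        pts[:, 2] = 1.0
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)


def femur_landmarks():
    return LandmarkSet([Landmark("FHC", [0, 400, 0]), Landmark("LE", [30, 0, 0]),
                        Landmark("ME", [-30, 0, 0])])


class TestFrames:
    def test_axis_aligned_femur(self):
        f = build_segment_frame(femur_landmarks(), "femur")
        np.testing.assert_allclose(f.origin, 0, atol=1e-12)
        np.testing.assert_allclose(f.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.z_axis, [0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize("segment,names", [
        ("femur", ("FHC", "LE", "ME")),
        ("tibia", ("TT", "LM", "MM")),
        ("pelvis", ("LASIS", "RASIS", "LPSIS", "RPSIS")),
    ])
    def test_orthonormal_right_handed_random(self, segment, names, rng):
        for _ in range(25):
            lms = LandmarkSet([Landmark(n, rng.normal(0, 100, 3)) for n in names])
            try:
                f = build_segment_frame(lms, segment)
            except DegenerateGeometryError:
                continue
            A = f.axes
            np.testing.assert_allclose(A @ A.T, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(np.cross(f.x_axis, f.y_axis), f.z_axis,
                                       atol=1e-9)

    def test_equivariance_under_rigid_motion(self, rng):
        lms = femur_landmarks()
        f = build_segment_frame(lms, "femur")
        T = random_rigid(rng)
        f2 = build_segment_frame(lms.transformed(T), "femur")
        np.testing.assert_allclose(f2.origin, T.apply(f.origin), atol=1e-9)
        np.testing.assert_allclose(f2.axes, f.axes @ T.rotation.T, atol=1e-9)

    def test_missing_landmark(self):
        with pytest.raises(MissingLandmarkError):
            build_segment_frame(LandmarkSet([Landmark("LE", [1, 0, 0])]), "femur")

    def test_degenerate_axes(self):
        lms = LandmarkSet([Landmark("FHC", [0, 400, 0]), Landmark("LE", [0, 10, 0]),
                           Landmark("ME", [0, -10, 0])])
        with pytest.raises(DegenerateGeometryError):
            build_segment_frame(lms, "femur")


class TestLandmarkIO:
    def test_csv_round_trip(self, tmp_path, rng):
        lms = LandmarkSet([Landmark("GT", rng.normal(0, 10, 3), "skin"),
                           Landmark("ATP", rng.normal(0, 10, 3), "bone", "sliding")])
        path = tmp_path / "lm.csv"
        lms.to_csv(path)
        back = LandmarkSet.from_csv(path)
        assert back.names == lms.names
        np.testing.assert_allclose(back.position("GT"), lms.position("GT"))
        assert back["ATP"].kind == "sliding"

    def test_json_round_trip(self, tmp_path):
        lms = LandmarkSet([Landmark("LE", [1.5, 2.5, 3.5])])
        path = tmp_path / "lm.json"
        lms.to_json(path)
        np.testing.assert_allclose(LandmarkSet.from_json(path).position("LE"),
                                   [1.5, 2.5, 3.5])

    def test_duplicate_name_rejected(self):
        with pytest.raises(InputError):
            LandmarkSet([Landmark("GT", [0, 0, 0]), Landmark("GT", [1, 1, 1])])

    def test_sliding_restricted(self):
        with pytest.raises(InputError):
            Landmark("GT", [0, 0, 0], kind="sliding")


class TestProximity:
    def test_closest_point_exact_on_known_triangle(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)
        from limbssm.proximity import closest_point_on_triangles
        queries = np.array([[0.2, 0.2, 5.0],   # interior
                            [-1.0, -1.0, 0.0],  # vertex A
                            [0.5, -2.0, 1.0],   # edge AB
                            [2.0, 2.0, 0.0]])   # edge BC
        expected = np.array([[0.2, 0.2, 0.0], [0, 0, 0], [0.5, 0, 0], [0.5, 0.5, 0]])
        out = closest_point_on_triangles(queries, np.repeat(tri, 4, axis=0))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_matches_brute_force(self, ellipsoid, rng):
        query = SurfaceQuery(ellipsoid)
        pts = rng.normal(0, 60, (50, 3))
        closest, dist = query.closest(pts)
        from limbssm.proximity import closest_point_on_triangles
        tris = np.asarray(ellipsoid.triangles)
        for p, d in zip(pts, dist):
            cand = closest_point_on_triangles(np.tile(p, (len(tris), 1)), tris)
            brute = np.min(np.linalg.norm(cand - p, axis=1))
            assert abs(d - brute) < 1e-9
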
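"""Geometric primitive fits: plane, glenoid ellipse, sphere, shaft axis."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from glenokin import (
    AmbiguousAxisError,
    DegenerateInputError,
    NearCircularWarning,
    fit_glenoid_cs,
    fit_plane,
    fit_shaft_axis,
    fit_sphere,
)
from conftest import make_ellipse_contour, random_rigid


class TestPlane:
    def test_coplanar_points_recover_plane_exactly(self, rng):
        pts = np.column_stack([rng.normal(size=(30, 2)), np.full(30, 2.0)])
        fit = fit_plane(pts)
        assert abs(abs(fit.normal[2]) - 1.0) < 1e-12
        assert abs(fit.centroid[2] - 2.0) < 1e-12
        assert fit.rms_residual < 1e-12

    def test_tetrahedron_residual_matches_eigen_oracle(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        fit = fit_plane(pts)
        # oracle: smallest eigenvalue of the scatter matrix
        centred = pts - pts.mean(axis=0)
        eigvals = np.linalg.eigvalsh(centred.T @ centred / len(pts))
        assert fit.rms_residual > 0
        assert np.isclose(fit.rms_residual, np.sqrt(eigvals[0]), atol=1e-12)

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([[0.0, 0, 0], [1, 0, 0]]),
            np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]]),
        ],
        ids=["two_points", "collinear"],
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(DegenerateInputError):
            fit_plane(pts)

    def test_normal_orientation_hint(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(20, 2)), np.zeros(20)])
        fit = fit_plane(pts, toward=[0, 0, 5.0])
        assert fit.normal[2] > 0


class TestGlenoidCS:
    def test_axis_aligned_ellipse_recovery(self):
        contour = make_ellipse_contour(14.0, 10.0)
        cs = fit_glenoid_cs(contour, superior_hint=[0, 20, 0], anterior_hint=[20, 0, 0])
        assert np.allclose(cs.center, 0, atol=1e-9)
        assert np.isclose(cs.semi_major, 14.0, atol=1e-6)
        assert np.isclose(cs.semi_minor, 10.0, atol=1e-6)
        assert np.allclose(cs.axis_y, [0, 1, 0], atol=1e-6)
        assert np.allclose(cs.axis_x, [1, 0, 0], atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_construct_then_recover_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        contour = make_ellipse_contour(17.5, 12.5)
        t = random_rigid(rng)
        cs = fit_glenoid_cs(
            t.apply(contour),
            superior_hint=t.apply([[0, 30.0, 0]])[0],
            anterior_hint=t.apply([[30.0, 0, 0]])[0],
        )
        assert np.allclose(cs.center, t.translation, atol=1e-6)
        assert np.isclose(cs.semi_major, 17.5, atol=1e-6)
        assert np.isclose(cs.semi_minor, 12.5, atol=1e-6)
        assert np.allclose(cs.axis_y, t.rotation @ [0, 1, 0], atol=1e-6)
        assert np.allclose(cs.axis_x, t.rotation @ [1, 0, 0], atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_axes_form_right_handed_orthonormal_triad(self, seed):
        rng = np.random.default_rng(seed + 100)
        contour = make_ellipse_contour(16.0, 11.0) + rng.normal(0, 0.3, (36, 3))
        t = random_rigid(rng)
        cs = fit_glenoid_cs(
            t.apply(contour),
            superior_hint=t.apply([[3.0, 25.0, 1.0]])[0],
            anterior_hint=t.apply([[25.0, -2.0, 0.5]])[0],
        )
        for a, b in [(cs.axis_x, cs.axis_y), (cs.axis_x, cs.axis_z), (cs.axis_y, cs.axis_z)]:
            assert abs(a @ b) < 1e-9
        for a in (cs.axis_x, cs.axis_y, cs.axis_z):
            assert abs(np.linalg.norm(a) - 1.0) < 1e-9
        assert np.allclose(np.cross(cs.axis_x, cs.axis_y), cs.axis_z, atol=1e-9)
        assert cs.semi_major >= cs.semi_minor > 0

    def test_circle_contour_warns_near_circular(self):
        contour = make_ellipse_contour(10.0, 10.0)
        with pytest.warns(NearCircularWarning):
            cs = fit_glenoid_cs(contour, [0, 20, 0], [20, 0, 0])
        assert np.isclose(cs.semi_major, 10.0, atol=1e-6)
        assert np.isclose(cs.semi_minor, 10.0, atol=1e-6)

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateInputError):
            fit_glenoid_cs(make_ellipse_contour(n=5), [0, 1, 0], [1, 0, 0])

    def test_hint_signs_flip_axes(self):
        contour = make_ellipse_contour(14.0, 10.0)
        cs = fit_glenoid_cs(contour, superior_hint=[0, -20, 0], anterior_hint=[-20, 0, 0])
        assert np.allclose(cs.axis_y, [0, -1, 0], atol=1e-6)
        assert np.allclose(cs.axis_x, [-1, 0, 0], atol=1e-6)
        # still right-handed via the cross product
        assert np.allclose(np.cross(cs.axis_x, cs.axis_y), cs.axis_z, atol=1e-12)


class TestSphere:
    def test_exact_octahedral_points(self):
        pts = 24.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, 0, atol=1e-9)
        assert np.isclose(fit.radius, 24.0, atol=1e-9)
        assert fit.rms_residual < 1e-9

    def test_hemispherical_cap_recovery(self, rng):
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = dirs[dirs[:, 2] > 0]  # cap only
        pts = np.array([1.0, 2.0, 3.0]) + 24.0 * dirs
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, [1, 2, 3], atol=1e-6)
        assert np.isclose(fit.radius, 24.0, atol=1e-6)

    def test_coplanar_points_raise(self, rng):
        pts = np.column_stack([rng.normal(size=(10, 2)), np.zeros(10)])
        with pytest.raises(DegenerateInputError):
            fit_sphere(pts)

    def test_noisy_fit_matches_nonlinear_oracle(self, rng):
        dirs = rng.normal(size=(300, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sigma = 0.1
        pts = np.array([5.0, -3.0, 2.0]) + 24.0 * dirs + rng.normal(0, sigma, (300, 3))
        fit = fit_sphere(pts)

        def residual(params):
            return np.linalg.norm(pts - params[:3], axis=1) - params[3]

        oracle = least_squares(residual, x0=[0.0, 0.0, 0.0, 20.0]).x
        assert np.allclose(fit.center, oracle[:3], atol=1e-6)
        assert np.isclose(fit.radius, oracle[3], atol=1e-6)
        assert np.linalg.norm(fit.center - [5, -3, 2]) < sigma


class TestShaftAxis:
    @staticmethod
    def _cylinder(n_len=20, n_seg=12, radius=12.0, length=120.0):
        z = np.linspace(0, length, n_len)
        ph = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
        zz, pp = np.meshgrid(z, ph)
        return np.column_stack(
            [radius * np.cos(pp.ravel()), radius * np.sin(pp.ravel()), zz.ravel()]
        )

    def test_cylinder_axis(self):
        axis = fit_shaft_axis(self._cylinder())
        assert abs(abs(axis.direction[2]) - 1.0) < 1e-3

    @pytest.mark.parametrize("seed", range(3))
    def test_rotated_cylinder_axis(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        axis = fit_shaft_axis(t.apply(self._cylinder()))
        expected = t.rotation @ [0, 0, 1]
        assert min(
            np.linalg.norm(axis.direction - expected),
            np.linalg.norm(axis.direction + expected),
        ) < 1e-3

    def test_sign_toward_hint(self):
        axis = fit_shaft_axis(self._cylinder(), toward=[0, 0, 500.0])
        assert axis.direction[2] > 0

    def test_isotropic_cloud_raises(self, rng):
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        with pytest.raises(AmbiguousAxisError):
            fit_shaft_axis(24.0 * dirs)


@pytest.mark.parametrize("seed", range(3))
def test_sphere_fit_transforms_covariantly_under_rigid_motion(seed, rng):
    """Fit outputs must move with the input points (rigid invariance)."""
    local = np.random.default_rng(seed)
    dirs = local.normal(size=(150, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.array([1.0, 2.0, 3.0]) + 24.0 * dirs
    t = random_rigid(local)
    f0 = fit_sphere(pts)
    f1 = fit_sphere(t.apply(pts))
    assert np.allclose(f1.center, t.apply(f0.center[None])[0], atol=1e-6)
    assert np.isclose(f1.radius, f0.radius, atol=1e-6)
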
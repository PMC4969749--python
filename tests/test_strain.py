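"""Strain tensors, projection onto curves, field differentiation/sampling."""

import numpy as np
import pytest

from neurostrain import (
    Curve3D,
    DisplacementField,
    FarFieldStrain,
    StrainField,
    bleb_local_strain,
    green_lagrange_from_displacement,
    local_strain_profile,
    mean_strains,
    project_strain,
    resample_arclength,
    sample_strain_at_curve,
    tangent_frames,
    uniform_compression_tensor,
)

from conftest import random_symmetric_tensor, semicircle_curve


def brute_force_projection(t, E):
    """Oracle: rotate E into a frame with first axis t and read components."""
    t = np.asarray(t, dtype=float)
    # complete an orthonormal basis by Gram-Schmidt on random vectors
    rng = np.random.default_rng(999)
    while True:
        a = rng.normal(size=3)
        n = a - (a @ t) * t
        if np.linalg.norm(n) > 1e-6:
            n /= np.linalg.norm(n)
            break
    b = np.cross(t, n)
    Q = np.stack([t, n, b])
    El = Q @ E @ Q.T
    return El[0, 0], np.hypot(El[0, 1], El[0, 2])


class TestUniformCompressionTensor:
    @pytest.mark.parametrize(
        "applied,ratio,expected_diag",
        [
            (0.30, 0.0, (0.0, 0.0, -0.30)),
            (0.0, 0.5, (0.0, 0.0, 0.0)),
            (0.38, 0.5, (0.19, 0.19, -0.38)),
        ],
    )
    def test_diagonal_components(self, applied, ratio, expected_diag):
        E = uniform_compression_tensor(applied, ratio).E
        assert np.allclose(np.diag(E), expected_diag)
        assert np.allclose(E, np.diag(np.diag(E)))

    def test_rejects_strain_at_or_above_one(self):
        with pytest.raises(ValueError):
            uniform_compression_tensor(1.0)
        with pytest.raises(ValueError):
            uniform_compression_tensor(-0.1)


class TestProjectStrain:
    def test_aligned_tangent_is_eigenvector(self):
        E = uniform_compression_tensor(0.30)
        e_c, e_s = project_strain((0, 0, 1), E)
        assert e_c == pytest.approx(-0.30)
        assert e_s == pytest.approx(0.0, abs=1e-15)

    def test_45_degree_orientation_against_rotation_oracle(self):
        t = np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)])
        E = uniform_compression_tensor(0.30)
        e_c, e_s = project_strain(t, E)
        assert e_c == pytest.approx(-0.15)
        assert e_s == pytest.approx(0.15)
        oc, os_ = brute_force_projection(t, E.E)
        assert e_c == pytest.approx(oc)
        assert e_s == pytest.approx(os_)

    def test_isotropic_tensor_has_no_shear(self, rng):
        c = 0.2
        for _ in range(5):
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            e_c, e_s = project_strain(t, FarFieldStrain(c * np.eye(3)))
            assert e_c == pytest.approx(c)
            assert e_s == pytest.approx(0.0, abs=1e-12)

    def test_random_tensors_match_rotation_oracle(self, rng):
        for _ in range(20):
            E = random_symmetric_tensor(rng)
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            e_c, e_s = project_strain(t, E)
            oc, os_ = brute_force_projection(t, E)
            assert e_c == pytest.approx(oc, abs=1e-12)
            assert e_s == pytest.approx(os_, abs=1e-12)

    def test_shear_vanishes_iff_tangent_is_eigenvector(self, rng):
        for _ in range(20):
            E = random_symmetric_tensor(rng)
            eigvals, eigvecs = np.linalg.eigh(E)
            for k in range(3):
                _, e_s = project_strain(eigvecs[:, k], E)
                assert e_s == pytest.approx(0.0, abs=1e-9)
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            # a generic tangent of a tensor with distinct eigenvalues shears
            if np.min(np.diff(eigvals)) > 1e-3 and np.min(
                np.abs(eigvecs.T @ t)
            ) > 1e-2:
                _, e_s = project_strain(t, E)
                assert e_s > 1e-6

    def test_non_unit_tangent_rejected(self):
        with pytest.raises(ValueError):
            project_strain((0, 0, 2), uniform_compression_tensor(0.3))


class TestLocalStrainProfile:
    def test_trace_conserved_under_frame_rotation(self, rng):
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0)
        curve = Curve3D(pts)
        E = random_symmetric_tensor(rng)
        profile = local_strain_profile(curve, FarFieldStrain(E))
        traces = np.trace(profile.E_local, axis1=-2, axis2=-1)
        assert np.allclose(traces, np.trace(E), atol=1e-9)

    def test_projections_independent_of_normal_choice(self, rng):
        pts = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        curve = Curve3D(pts)
        E = FarFieldStrain(random_symmetric_tensor(rng))
        f1 = tangent_frames(curve)
        # a different transported frame: seed the normal differently
        f2 = tangent_frames(curve, initial_normal=rng.normal(size=3))
        p1 = local_strain_profile(curve, E, frames=f1)
        p2 = local_strain_profile(curve, E, frames=f2)
        assert np.allclose(p1.E_c, p2.E_c, atol=1e-12)
        assert np.allclose(p1.E_s, p2.E_s, atol=1e-12)


class TestMeanStrains:
    def test_straight_neurite_full_compression(self, straight_z_curve):
        summary = mean_strains(straight_z_curve, uniform_compression_tensor(0.30))
        assert summary.mean_Ec == pytest.approx(0.30)
        assert summary.mean_Es == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_matches_analytic_average(self):
        summary = mean_strains(
            semicircle_curve(n=4001), uniform_compression_tensor(0.30)
        )
        assert summary.mean_Ec == pytest.approx(0.15, rel=1e-4)
        assert summary.mean_Es == pytest.approx(0.3 / np.pi, rel=1e-4)

    def test_zero_tensor_gives_zero(self, straight_z_curve):
        summary = mean_strains(straight_z_curve, uniform_compression_tensor(0.0))
        assert summary.mean_Ec == 0.0
        assert summary.mean_Es == 0.0

    def test_quadrature_error_decreases_with_spacing(self):
        fine = semicircle_curve(n=20001)
        exact = 0.15
        errors = []
        for spacing in (2.0, 0.5, 0.1):
            curve = resample_arclength(fine, spacing)
            s = mean_strains(curve, uniform_compression_tensor(0.30))
            errors.append(abs(s.mean_Ec - exact))
        assert errors[0] > errors[1] > errors[2]
        # spacing L/1000 ≈ 0.0314 for this arc
        curve = resample_arclength(fine, fine.length / 1000)
        s = mean_strains(curve, uniform_compression_tensor(0.30))
        assert abs(s.mean_Ec - exact) < 1e-4


class TestGreenLagrange:
    def _affine_field(self, A, shape=(6, 7, 8), spacing=(1.0, 2.0, 0.5)):
        axes = [spacing[k] * np.arange(shape[k]) for k in range(3)]
        xx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        u = xx @ A.T
        return DisplacementField(u=u, spacing=spacing)

    def test_uniaxial_stretch_closed_form(self):
        lam = 0.7
        A = np.diag([0.0, 0.0, lam - 1.0])
        field = green_lagrange_from_displacement(self._affine_field(A))
        expected = (lam**2 - 1) / 2
        assert np.allclose(field.E[..., 2, 2], expected, atol=1e-12)
        assert np.max(np.abs(field.E[..., :2, :])) < 1e-12

    def test_zero_displacement_zero_strain(self):
        field = green_lagrange_from_displacement(
            DisplacementField(u=np.zeros((4, 4, 4, 3)), spacing=(1, 1, 1))
        )
        assert np.max(np.abs(field.E)) == 0.0

    def test_rigid_rotation_produces_no_strain(self):
        theta = 1e-3
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        field = green_lagrange_from_displacement(self._affine_field(R - np.eye(3)))
        assert np.max(np.abs(field.E)) < 1e-6

    def test_random_affine_matches_tensor_closed_form(self, rng):
        A = rng.normal(scale=0.1, size=(3, 3))
        field = green_lagrange_from_displacement(self._affine_field(A))
        F = np.eye(3) + A
        expected = 0.5 * (F.T @ F - np.eye(3))
        assert np.max(np.abs(field.E - expected)) < 1e-12

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            DisplacementField(u=np.zeros((1, 4, 4, 3)), spacing=(1, 1, 1))


class TestSampleStrainAtCurve:
    def _linear_field(self):
        # E_33 varies linearly in x3; grid spans [0, 10]^3
        z = np.arange(11.0)
        E = np.zeros((11, 11, 11, 3, 3))
        E[..., 2, 2] = -0.03 * z[None, None, :]
        return StrainField(E=E, spacing=(1.0, 1.0, 1.0))

    def test_uniform_field_constant_tensors(self, straight_z_curve):
        E = np.zeros((5, 5, 12, 3, 3))
        E[..., 2, 2] = -0.3
        field = StrainField(E=E, spacing=(1.0, 1.0, 1.0))
        curve = Curve3D(np.column_stack([np.ones(5), np.ones(5), np.linspace(0, 10, 5)]))
        tensors = sample_strain_at_curve(field, curve)
        assert np.allclose(tensors[:, 2, 2], -0.3)

    def test_linear_field_interpolates_midpoint(self):
        field = self._linear_field()
        curve = Curve3D(np.array([[5.0, 5.0, 0.0], [5.0, 5.0, 5.5], [5.0, 5.0, 10.0]]))
        tensors = sample_strain_at_curve(field, curve)
        assert tensors[1, 2, 2] == pytest.approx(-0.03 * 5.5, abs=1e-12)

    def test_point_outside_grid_names_index(self):
        field = self._linear_field()
        curve = Curve3D(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 15.0]]))
        with pytest.raises(ValueError, match="point 1"):
            sample_strain_at_curve(field, curve)

    def test_mean_strains_from_uniform_field_match_tensor(self, straight_z_curve):
        E = np.zeros((3, 3, 12, 3, 3))
        E[..., 2, 2] = -0.3
        field = StrainField(E=E, spacing=(5.0, 5.0, 1.0))
        curve = Curve3D(
            np.column_stack([np.full(11, 5.0), np.full(11, 5.0), np.linspace(0, 10, 11)])
        )
        summary = mean_strains(curve, field)
        assert summary.mean_Ec == pytest.approx(0.30)


class TestBlebLocalStrain:
    def _profile(self, e_s):
        s = np.linspace(0, 20, len(e_s))
        e_c = -0.1 * np.ones_like(s)
        El = np.zeros((len(s), 3, 3))
        from neurostrain import LocalStrainProfile

        return LocalStrainProfile(arclengths=s, E_local=El, E_c=e_c, E_s=e_s)

    def test_constant_profile_returns_constant(self):
        profile = self._profile(np.full(21, 0.12))
        out = bleb_local_strain(profile, [5.0, 10.0], window=2.0)
        assert np.allclose(out[:, 0], 0.1)
        assert np.allclose(out[:, 1], 0.12)

    def test_triangular_peak_inside_window_detected(self):
        s = np.linspace(0, 20, 201)
        e_s = np.maximum(0.0, 0.2 - 0.4 * np.abs(s - 10.0))  # peak 0.2 at s=10
        profile = self._profile(e_s)
        out = bleb_local_strain(profile, [10.5], window=2.0)
        assert out[0, 1] == pytest.approx(0.2)

    def test_bleb_at_curve_start_uses_one_sided_window(self):
        profile = self._profile(np.full(21, 0.05))
        out = bleb_local_strain(profile, [0.0], window=2.0)
        assert out[0, 1] == pytest.approx(0.05)

    def test_bleb_outside_curve_rejected(self):
        profile = self._profile(np.full(21, 0.05))
        with pytest.raises(ValueError):
            bleb_local_strain(profile, [25.0], window=2.0)
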
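import numpy as np
import pytest
from scipy.stats import special_ortho_group

from enterospring.errors import InvalidParameterError, InvertedElementError
from enterospring.geometry import IntestineModelSpec, WallPartition
from enterospring.materials import LayerMaterial
from enterospring.mechanics_core import (
    DeformationState,
    cauchy_stress,
    cauchy_stress_finite_difference,
    layered_doubling_force,
    layered_force_breakdown,
    strain_energy,
    uniaxial_layer_response,
)

C_REF, D_REF = 0.44, 0.0456


def random_deformation_gradients(n, seed=0, spread=0.4):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(3) + spread * rng.standard_normal((3, 3))
        if 0.5 < np.linalg.det(F) < 2.0:
            out.append(F)
    return out


class TestStrainEnergy:
    def test_zero_at_identity(self):
        assert strain_energy(np.eye(3), C_REF, D_REF) == 0.0

    def test_zero_for_rotations(self):
        for i in range(5):
            Q = special_ortho_group.rvs(3, random_state=i)
            assert abs(strain_energy(Q, C_REF, D_REF)) < 1e-12

    def test_isochoric_uniaxial_value(self):
        # F = diag(l, 1/sqrt(l), 1/sqrt(l)) at l=1.2, J=1, C=0.5, D->0
        lam = 1.2
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        expected = 0.5 * (lam ** 2 + 2.0 / lam - 3.0)
        assert strain_energy(F, 0.5, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_on_random_states(self):
        for F in random_deformation_gradients(50, seed=4):
            assert strain_energy(F, C_REF, D_REF) >= -1e-12

    def test_inverted_state_rejected(self):
        with pytest.raises(InvertedElementError):
            strain_energy(-np.eye(3), C_REF, D_REF)


class TestCauchyStress:
    def test_zero_at_identity(self):
        np.testing.assert_allclose(cauchy_stress(np.eye(3), C_REF, D_REF), 0.0)

    def test_matches_finite_difference_oracle(self):
        worst = 0.0
        for F in random_deformation_gradients(100, seed=0):
            s = cauchy_stress(F, C_REF, D_REF)
            s_fd = cauchy_stress_finite_difference(F, C_REF, D_REF)
            worst = max(worst, np.linalg.norm(s - s_fd) / np.linalg.norm(s))
        assert worst < 1e-6

    def test_pure_dilation(self):
        a = 1.2
        s = cauchy_stress(a * np.eye(3), C_REF, D_REF)
        expected = (a ** 3 - a ** -3) / D_REF
        np.testing.assert_allclose(s, expected * np.eye(3), rtol=1e-12)
        np.testing.assert_allclose(s - np.trace(s) / 3 * np.eye(3), 0.0,
                                   atol=1e-12)

    def test_symmetry_and_objectivity(self):
        for i, F in enumerate(random_deformation_gradients(20, seed=7)):
            s = cauchy_stress(F, C_REF, D_REF)
            np.testing.assert_allclose(s, s.T, atol=1e-12)
            Q = special_ortho_group.rvs(3, random_state=i)
            np.testing.assert_allclose(
                cauchy_stress(Q @ F, C_REF, D_REF), Q @ s @ Q.T, atol=1e-10)


class TestDeformationState:
    def test_identity_growth_means_total_equals_elastic(self):
        F = np.diag([1.3, 0.9, 1.1])
        st = DeformationState.from_deformation_gradient(F)
        np.testing.assert_allclose(st.F_total, st.F_elastic)
        np.testing.assert_allclose(st.G_growth, np.eye(3))
        assert st.J == pytest.approx(np.linalg.det(F))

    def test_lagrange_strain_definition(self):
        F = np.diag([2.0, 1.0, 1.0])
        st = DeformationState.from_deformation_gradient(F)
        np.testing.assert_allclose(st.E_lagrange, np.diag([1.5, 0.0, 0.0]))

    def test_explicit_identity_growth_matches_default(self):
        F = np.diag([1.4, 0.85, 1.05])
        a = DeformationState.from_deformation_gradient(F)
        b = DeformationState.from_deformation_gradient(F, G=np.eye(3))
        np.testing.assert_allclose(a.F_elastic, b.F_elastic)
        assert a.I1_bar == pytest.approx(b.I1_bar)


class TestUniaxialResponse:
    def test_reference_state_is_stress_free(self):
        m = LayerMaterial.from_young("x", 2.0, 0.49)
        st = uniaxial_layer_response(1.0, m)
        assert st.lambda_r == pytest.approx(1.0, abs=1e-10)
        assert st.sigma_zz == pytest.approx(0.0, abs=1e-10)

    def test_incompressible_closed_form(self):
        m = LayerMaterial.from_young("x", 4 * 0.5 * 1.5, 0.5)  # C = 0.5
        st = uniaxial_layer_response(2.0, m)
        assert st.nominal_zz == pytest.approx(1.75, rel=1e-12)

    def test_incompressible_limit_convergence(self):
        C = 0.5
        target = 2 * C * (2.0 - 0.25)
        gaps = []
        for nu in (0.49, 0.499, 0.4999):
            m = LayerMaterial.from_young("x", 4 * C * (1 + nu), nu)
            st = uniaxial_layer_response(2.0, m)
            gaps.append(abs(st.nominal_zz - target) / target)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[-1] < 1e-3

    def test_near_isochoric_at_nu_049(self):
        m = LayerMaterial.from_young("x", 2.63, 0.49)
        st = uniaxial_layer_response(2.0, m)
        assert abs(st.J - 1.0) < 0.05

    def test_invalid_stretch(self):
        m = LayerMaterial.from_young("x", 2.0, 0.49)
        with pytest.raises(InvalidParameterError):
            uniaxial_layer_response(-1.0, m)


class TestLayeredDoublingForce:
    def test_single_material_incompressible_area_scaling(self):
        # one material everywhere, C=0.5 incompressible: F = 1.75 MPa * area
        m = LayerMaterial.from_young("x", 3.0, 0.5)
        mats = {k: m for k in ("mucosa", "submucosa", "muscularis")}
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        area = spec.layer_areas_mm2().sum()
        force = layered_doubling_force(spec, mats)
        assert force == pytest.approx(1.75 * area, rel=1e-12)

    def test_force_scales_with_area_uniform_material(self):
        # iso-strain additivity: with one material in all layers the
        # force is exactly proportional to the total cross-section area
        m = LayerMaterial.from_young("x", 2.63, 0.49)
        mats = {k: m for k in ("mucosa", "submucosa", "muscularis")}
        s1 = IntestineModelSpec(inner_radius=1.0, wall_thickness=1.0)
        s2 = IntestineModelSpec(inner_radius=2.0, wall_thickness=1.0)
        f1 = layered_doubling_force(s1, mats)
        f2 = layered_doubling_force(s2, mats)
        ratio = s2.layer_areas_mm2().sum() / s1.layer_areas_mm2().sum()
        assert f2 / f1 == pytest.approx(ratio, rel=1e-9)

    def test_monotone_in_stretch(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        forces = [layered_doubling_force(spec, human_materials, stretch=s)
                  for s in np.linspace(1.05, 2.5, 8)]
        assert all(b > a for a, b in zip(forces, forces[1:]))

    def test_breakdown_sums_to_total(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.5, wall_thickness=2.5)
        parts = layered_force_breakdown(spec, human_materials)
        assert sum(parts.values()) == pytest.approx(
            layered_doubling_force(spec, human_materials), rel=1e-12)
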
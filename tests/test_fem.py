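import numpy as np
import pytest

from enterospring.errors import MeshingError, SolverFailureError
from enterospring.fem import assembly as fasm
from enterospring.fem import solver as fsol
from enterospring.fem.mesh import (
    MeshResolution,
    build_mesh,
    element_layer_arrays,
    reference_jacobians,
)
from enterospring.fem.postprocess import extract_wall_profiles
from enterospring.fem.vtkio import solution_cell_data, write_legacy_vtk
from enterospring.geometry import IntestineModelSpec, MesenteryOptions
from enterospring.materials import LayerMaterial
from enterospring.mechanics_core import layered_doubling_force

from conftest import make_cube_mesh

MUCOSA = LayerMaterial.from_young("mucosa", 2.63, 0.49)


def cube_materials():
    return {"mucosa": MUCOSA}


class TestMeshBuild:
    def test_element_count_no_mesentery(self):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        mesh = build_mesh(spec, MeshResolution(n_theta=16, n_z=8))
        assert mesh.n_elems == 3 * 16 * 8

    def test_reference_jacobians_positive(self):
        spec = IntestineModelSpec(inner_radius=0.25, wall_thickness=3.0,
                                  mesentery=MesenteryOptions())
        mesh = build_mesh(spec, MeshResolution(n_theta=12, n_z=3))
        assert reference_jacobians(mesh).min() > 0

    def test_layer_radii_match_partition(self):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        mesh = build_mesh(spec, MeshResolution(n_theta=8, n_z=1))
        radii = np.unique(np.round(np.hypot(
            mesh.nodes[:, 0], mesh.nodes[:, 1]), 9))
        np.testing.assert_allclose(radii, spec.radii_mm(), atol=1e-9)

    def test_mesentery_adds_tied_sheet(self):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0,
                                  mesentery=MesenteryOptions())
        res = MeshResolution(n_theta=8, n_z=2, n_mesentery_height=3)
        mesh = build_mesh(spec, res)
        assert (mesh.layer_tags == "mesentery").sum() == 3 * 2
        assert len(mesh.ties) == 2 * (2 + 1)  # 2 thickness rows x (n_z+1)
        assert "mesentery_base" in mesh.node_sets
        # every tie master lies on the outer wall at theta = 270 deg
        for slave, master in mesh.ties:
            x, y, _ = mesh.nodes[master]
            assert x == pytest.approx(0.0, abs=1e-9)
            assert y == pytest.approx(-12.0, abs=1e-9)

    def test_bad_theta_count_rejected(self):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        with pytest.raises(MeshingError):
            build_mesh(spec, MeshResolution(n_theta=10))


class TestAssembly:
    def test_zero_displacement_zero_residual(self, cube_mesh):
        mesh, _, _ = cube_mesh
        pre = fasm.precompute(mesh)
        C_e, D_e = element_layer_arrays(mesh, cube_materials())
        f = fasm.internal_force(mesh, pre, np.zeros_like(mesh.nodes), C_e, D_e)
        np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_rigid_translation_zero_force(self, cube_mesh):
        mesh, _, _ = cube_mesh
        pre = fasm.precompute(mesh)
        C_e, D_e = element_layer_arrays(mesh, cube_materials())
        u = np.tile([0.3, -0.2, 0.5], (mesh.n_nodes, 1))
        f = fasm.internal_force(mesh, pre, u, C_e, D_e)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_force_is_energy_gradient(self, cube_mesh):
        mesh, _, _ = cube_mesh
        pre = fasm.precompute(mesh)
        C_e, D_e = element_layer_arrays(mesh, cube_materials())
        rng = np.random.default_rng(5)
        u = 0.05 * rng.standard_normal(mesh.nodes.shape)
        f = fasm.internal_force(mesh, pre, u, C_e, D_e)
        h = 1e-30
        uc = u.astype(complex)
        for dof in rng.choice(3 * mesh.n_nodes, size=12, replace=False):
            up = uc.copy()
            up.reshape(-1)[dof] += 1j * h
            g = fasm.total_energy(mesh, pre, up, C_e, D_e).imag / h
            assert f[dof] == pytest.approx(g, rel=1e-12, abs=1e-12)

    def test_tangent_consistent_with_residual(self):
        # small distorted mesh, random state, directional finite difference
        mesh, _, _ = make_cube_mesh(n=2, L=2.0, perturb_interior=0.1)
        pre = fasm.precompute(mesh)
        C_e, D_e = element_layer_arrays(mesh, cube_materials())
        rng = np.random.default_rng(8)
        u = 0.04 * rng.standard_normal(mesh.nodes.shape)
        K = fasm.assemble_tangent(mesh, pre, u, C_e, D_e)
        v = rng.standard_normal(3 * mesh.n_nodes)
        v /= np.linalg.norm(v)
        eps = 1e-6
        fp = fasm.internal_force(mesh, pre, u + eps * v.reshape(-1, 3), C_e, D_e)
        fm = fasm.internal_force(mesh, pre, u - eps * v.reshape(-1, 3), C_e, D_e)
        fd = (fp - fm) / (2 * eps)
        assert np.linalg.norm(K @ v - fd) / np.linalg.norm(fd) < 1e-5


class TestSolver:
    def test_patch_test_uniform_gradient(self):
        mesh, idx, boundary = make_cube_mesh(n=2, perturb_interior=0.13)
        A = np.array([[0.10, 0.03, 0.0], [0.02, -0.04, 0.01], [0.0, 0.05, 0.08]])
        bcs = fsol.BoundaryConditionSet(inner_no_twist=False)
        for n in boundary:
            u = A @ mesh.nodes[n]
            for ci, comp in enumerate("xyz"):
                bcs.nodal_prescribed.append((n, comp, float(u[ci])))
        sol = fsol.solve_static(mesh, bcs, cube_materials(),
                                fsol.SolverOptions(n_increments=1))
        F = fasm.deformation_gradients(sol.pre, sol.u[mesh.elems])
        assert np.abs(F - (np.eye(3) + A)).max() < 1e-10

    def test_zero_prescribed_displacement_zero_reaction(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        mesh = build_mesh(spec, MeshResolution(n_theta=8, n_z=2))
        bcs = fsol.default_bcs(mesh, 0.0)
        sol = fsol.solve_static(mesh, bcs, human_materials,
                                fsol.SolverOptions(n_increments=1))
        assert abs(sol.reaction_end) < 1e-9

    def test_free_cylinder_matches_semi_analytic(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        res = fsol.find_doubling_force(
            spec, human_materials, MeshResolution(n_theta=16, n_z=2))
        f_sa = layered_doubling_force(spec, human_materials)
        assert abs(res.force - f_sa) / f_sa < 0.03

    def test_end_reactions_balance(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        res = fsol.find_doubling_force(
            spec, human_materials, MeshResolution(n_theta=8, n_z=2))
        assert abs(res.solution.reaction_end
                   + res.solution.reaction_symmetry) < 1e-6

    def test_no_volumetric_locking(self):
        # nu = 0.49 vs 0.45 must differ smoothly, not by orders of magnitude
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        forces = {}
        for nu in (0.45, 0.49):
            mats = {k: LayerMaterial.from_young(k, 2.63, nu)
                    for k in ("mucosa", "submucosa", "muscularis")}
            forces[nu] = fsol.find_doubling_force(
                spec, mats, MeshResolution(n_theta=8, n_z=2)).force
        assert abs(forces[0.49] - forces[0.45]) / forces[0.45] < 0.15

    def test_mesentery_solution_converges(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0,
                                  mesentery=MesenteryOptions())
        res = fsol.find_doubling_force(
            spec, human_materials,
            MeshResolution(n_theta=8, n_z=2, n_mesentery_height=2))
        assert res.solution.converged
        assert res.force > 0

    def test_solver_failure_carries_diagnostics(self, human_materials):
        spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
        mesh = build_mesh(spec, MeshResolution(n_theta=8, n_z=2))
        bcs = fsol.default_bcs(mesh, mesh.z_length)
        opts = fsol.SolverOptions(max_iterations=1, max_halvings=1)
        with pytest.raises(SolverFailureError) as exc:
            fsol.solve_static(mesh, bcs, human_materials, opts)
        assert "history" in exc.value.diagnostics


@pytest.fixture(scope="module")
def small_solution(human_materials):
    spec = IntestineModelSpec(inner_radius=1.0, wall_thickness=2.0)
    return fsol.find_doubling_force(
        spec, human_materials, MeshResolution(n_theta=8, n_z=2))


class TestPostprocess:

    def test_profile_signs_under_tension(self, small_solution):
        prof = extract_wall_profiles(small_solution.solution)
        assert (prof["E_RR"] < 0).all()   # radial thinning
        assert (prof["E_TT"] < 0).all()   # circumferential contraction
        assert (prof["E_ZZ"] > 0).all()   # axial extension
        assert (prof["S_ZZ"] > 0).all()

    def test_profile_displacement_increases_outward(self, small_solution):
        prof = extract_wall_profiles(small_solution.solution)
        u = prof["u_mag_mm"].to_numpy()
        assert np.all(np.diff(u) > 0)

    def test_profile_ordered_by_radius_with_layers(self, small_solution):
        prof = extract_wall_profiles(small_solution.solution)
        assert prof["r_mm"].is_monotonic_increasing
        assert list(prof["layer"].unique()) == ["mucosa", "submucosa",
                                                "muscularis"]

    def test_lateral_stress_small_vs_axial(self, small_solution):
        # free lateral faces: radial/hoop Cauchy stress is tiny
        prof = extract_wall_profiles(small_solution.solution)
        assert prof["S_RR"].abs().max() < 0.02 * prof["S_ZZ"].max()

    def test_vtk_export_round_numbers(self, small_solution, tmp_path):
        sol = small_solution.solution
        path = tmp_path / "model.vtk"
        write_legacy_vtk(sol.mesh, path,
                         point_data={"displacement": sol.u},
                         cell_data=solution_cell_data(sol))
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {sol.mesh.n_nodes} double" in text
        assert f"CELL_TYPES {sol.mesh.n_elems}" in text
        assert any(line.startswith("VECTORS displacement") for line in text)
        assert any(line.startswith("SCALARS S_ZZ") for line in text)
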
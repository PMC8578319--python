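"""Hyperelastic constitutive law and quasistatic solver verification."""

import numpy as np
import pytest

from ventmech import fem, meshing
from ventmech.fem import (
    _Assembler,
    _batch_PA,
    _newton,
    PressureLoad,
    ROT_PLUS,
    ogden_energy,
    stress_and_tangent,
)


def random_F(rng, scale=0.15):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    F[2, :2] = F[:2, 2] = 0  # plane-strain block
    F[2, 2] = 1.0
    if np.linalg.det(F) <= 0.1:
        return random_F(rng, scale)
    return F


class TestEnergy:
    def test_reference_state_energy_and_stress_vanish(self):
        assert ogden_energy(np.eye(3), 0.5, 5.0) == 0.0
        P, _ = stress_and_tangent(np.eye(3), 0.5, 5.0)
        np.testing.assert_allclose(P, 0.0, atol=1e-14)

    def test_pure_dilatation_closed_form(self):
        """Volumetric term only: J = 1.1, kappa = 3.3 kPa gives
        Psi = 3.3/4 (1.1^2 - 1 - 2 ln 1.1)."""
        J = 1.1
        F = J ** (1 / 3) * np.eye(3)
        expected = 3.3 / 4.0 * (J**2 - 1 - 2 * np.log(J))
        for mu in (0.1, 0.34, 2.0):  # isochoric part must not contribute
            assert ogden_energy(F, mu, 3.3) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.01599, abs=5e-6)

    def test_simple_shear_closed_form(self):
        """Simple shear gamma: I1 = 3 + gamma^2, J = 1, so Psi = mu gamma^2/2."""
        gamma = 0.1
        F = np.eye(3)
        F[0, 1] = gamma
        assert ogden_energy(F, 0.34, 3.3) == pytest.approx(0.34 * gamma**2 / 2, rel=1e-12)
        assert ogden_energy(F, 0.34, 3.3) == pytest.approx(0.0017, abs=1e-8)

    def test_frame_indifference_under_rotation(self):
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        assert ogden_energy(R, 0.5, 5.0) == pytest.approx(0.0, abs=1e-14)
        P, _ = stress_and_tangent(R, 0.5, 5.0)
        np.testing.assert_allclose(P, 0.0, atol=1e-12)


class TestStressAndTangent:
    def test_stress_matches_finite_difference_gradient(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            F = random_F(rng)
            mu, kappa = 0.68, 6.6
            P, _ = stress_and_tangent(F, mu, kappa)
            eps = 1e-6
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += eps
                    Fm[i, j] -= eps
                    fd = (ogden_energy(Fp, mu, kappa) - ogden_energy(Fm, mu, kappa)) / (2 * eps)
                    assert P[i, j] == pytest.approx(fd, rel=2e-6, abs=1e-9)

    def test_tangent_matches_finite_difference_of_stress(self):
        rng = np.random.default_rng(1)
        F = random_F(rng)
        mu, kappa = 0.34, 3.3
        _, A = stress_and_tangent(F, mu, kappa)
        eps = 1e-6
        for k in range(3):
            for l in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[k, l] += eps
                Fm[k, l] -= eps
                fd = (stress_and_tangent(Fp, mu, kappa)[0] - stress_and_tangent(Fm, mu, kappa)[0]) / (2 * eps)
                np.testing.assert_allclose(A[:, :, k, l], fd, rtol=5e-5, atol=1e-8)

    def test_vectorized_batch_agrees_with_pointwise(self):
        rng = np.random.default_rng(2)
        F2 = np.eye(2) + 0.1 * rng.standard_normal((7, 2, 2))
        mu = np.full(7, 680.0)
        kappa = np.full(7, 6600.0)
        P, A = _batch_PA(F2, mu, kappa)
        for e in range(7):
            P3, A3 = stress_and_tangent(F2[e], 680.0, 6600.0)
            np.testing.assert_allclose(P[e], P3[:2, :2], rtol=1e-12)
            np.testing.assert_allclose(A[e], A3[:2, :2, :2, :2], rtol=1e-12)

    def test_inverted_state_rejected(self):
        F = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="inversion"):
            ogden_energy(F, 0.5, 5.0)


class TestSolver:
    def test_zero_load_gives_zero_displacement(self, default_mesh):
        mesh, bset = default_mesh
        disp = fem.solve_quasistatic(mesh, bset, loads=fem.LoadCase(p_lv=0.0, p_sas=0.0))
        np.testing.assert_allclose(disp.u, 0.0)

    def test_lame_annulus_oracle(self, annulus_mesh):
        """Pressurized thick-walled annulus with fixed outer boundary: the
        plane-strain closed form with equivalent small-strain moduli must be
        reproduced within 2% at small pressure."""
        mesh, bset = annulus_mesh
        p = 2.0
        disp = fem.solve_quasistatic(mesh, bset, loads=fem.LoadCase(p_lv=p, p_sas=0.0))
        mu, kappa = 680.0, 6600.0
        lam = kappa - 2 * mu / 3
        a, b = 10.0, 20.0
        A = -p / (2 * (lam + mu) + 2 * mu * b**2 / a**2)
        u_exact = A * a - A * b**2 / a
        wall = mesh.ring_nodes[0]
        ur = np.einsum("ni,ni->n", disp.u[wall], mesh.nodes[wall] / a)
        assert np.mean(ur) == pytest.approx(u_exact, rel=0.02)

    def test_patch_constant_stress_on_two_region_rectangle(self):
        """Uniform boundary pressure on a two-region rectangle with equal
        materials produces a spatially constant Cauchy stress -p I."""
        mesh = meshing.structured_rectangle_mesh(10.0, 6.0, 10, 6)
        ring = mesh.ring_nodes[0]
        edges = np.c_[ring, np.roll(ring, -1)]
        mu = np.full(len(mesh.triangles), 680.0)
        kappa = np.full(len(mesh.triangles), 6600.0)
        asm = _Assembler(mesh.nodes, mesh.triangles, mu, kappa)
        p = 50.0
        loads = [PressureLoad(edges, p, ROT_PLUS)]
        pins = []
        for target, dofs in (((0, 0), (0, 1)), ((10, 0), (1,)), ((0, 6), (0,))):
            n = int(np.argmin(np.linalg.norm(mesh.nodes - target, axis=1)))
            pins += [2 * n + d for d in dofs]
        u, hist = _newton(asm, loads, np.array(pins))
        assert hist[-1] < 1e-8
        F2 = asm.deformation(u)
        P, _ = _batch_PA(F2, mu, kappa)
        J = np.linalg.det(F2)
        sig = np.einsum("eij,ekj->eik", P, F2) / J[:, None, None]
        np.testing.assert_allclose(sig, np.tile(-p * np.eye(2), (len(sig), 1, 1)), atol=1e-8)

    def test_residual_equals_energy_gradient(self):
        """Assembled internal force must equal the finite-difference gradient
        of the total strain energy on a coarse mesh."""
        mesh = meshing.structured_rectangle_mesh(4.0, 3.0, 4, 3)
        mu = np.full(len(mesh.triangles), 680.0)
        kappa = np.full(len(mesh.triangles), 6600.0)
        asm = _Assembler(mesh.nodes, mesh.triangles, mu, kappa)
        rng = np.random.default_rng(3)
        u = 0.05 * rng.standard_normal(asm.ndof)
        f = asm.internal_force_only(u)
        eps = 1e-6
        for d in rng.choice(asm.ndof, size=10, replace=False):
            up, um = u.copy(), u.copy()
            up[d] += eps
            um[d] -= eps
            fd = (asm.total_energy(up) - asm.total_energy(um)) / (2 * eps)
            assert f[d] == pytest.approx(fd, rel=5e-5, abs=1e-8)

    def test_load_linearity_in_small_pressure_limit(self, annulus_mesh):
        mesh, bset = annulus_mesh
        d1 = fem.solve_quasistatic(mesh, bset, loads=fem.LoadCase(p_lv=0.5, p_sas=0.0))
        d2 = fem.solve_quasistatic(mesh, bset, loads=fem.LoadCase(p_lv=1.0, p_sas=0.0))
        ratio = np.linalg.norm(d2.u) / np.linalg.norm(d1.u)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_mirror_symmetric_subject_gives_mirror_symmetric_solution(
        self, default_solution, default_mesh, default_wall
    ):
        """The default subject is left-right symmetric; the wall displacement
        must be mirror-symmetric (to discretization tolerance, since the
        interior point cloud is not itself mirrored)."""
        mesh, _ = default_mesh
        disp, _ = default_solution
        from scipy.spatial import cKDTree

        coords = default_wall.coords
        u = disp.u[default_wall.node_indices]
        tree = cKDTree(coords)
        d, j = tree.query(np.c_[-coords[:, 0], coords[:, 1]])
        ok = d < 0.2 * mesh.target_edge_length
        assert ok.mean() > 0.5
        u_m = np.c_[-u[j[ok], 0], u[j[ok], 1]]
        umax = np.abs(disp.u).max()
        assert np.abs(u[ok] - u_m).max() < 0.03 * umax

    def test_empty_skull_set_rejected(self, default_mesh):
        mesh, bset = default_mesh
        bad = meshing.BoundarySets(
            ventricular_wall_edges=bset.ventricular_wall_edges,
            gm_wm_interface_edges=bset.gm_wm_interface_edges,
            gm_csf_interface_edges=bset.gm_csf_interface_edges,
            skull_nodes=np.array([], int),
        )
        with pytest.raises(ValueError, match="skull"):
            fem.solve_quasistatic(mesh, bad)


class TestKinematics:
    def test_zero_displacement_reference_state(self, default_mesh):
        mesh, _ = default_mesh
        disp = fem.DisplacementField(u=np.zeros_like(mesh.nodes))
        state = fem.kinematics(disp, mesh)
        np.testing.assert_allclose(state.C, np.tile(np.eye(3), (len(state.C), 1, 1)))
        np.testing.assert_allclose(state.E, 0.0, atol=1e-15)
        np.testing.assert_allclose(state.I1_bar, 3.0)

    def test_affine_displacement_reproduced_exactly(self, default_mesh):
        """Linear triangles reproduce affine fields exactly: u = (0.01 x, 0)
        gives F = diag(1.01, 1, 1) on every element."""
        mesh, _ = default_mesh
        u = np.zeros_like(mesh.nodes)
        u[:, 0] = 0.01 * mesh.nodes[:, 0]
        state = fem.kinematics(fem.DisplacementField(u=u), mesh)
        expected = np.diag([1.01, 1.0, 1.0])
        np.testing.assert_allclose(state.F, np.tile(expected, (len(state.F), 1, 1)), atol=1e-12)

    def test_isochoric_split_identity(self, default_solution):
        """det(Cbar) = 1 is an algebraic identity of the kinematic split."""
        _, state = default_solution
        np.testing.assert_allclose(np.linalg.det(state.Cbar), 1.0, atol=1e-10)
        assert np.all(state.J > 0)
        assert np.all(state.I1_bar >= 3.0 - 1e-12)
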
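"""FE core verification: element oracle, patch test, bar, beam, cables."""

import numpy as np
import pytest

from spinefe.errors import FESingularError
from spinefe.fe import FEModel, FEOperator, principal_stresses, solve_static
from spinefe.materials import MaterialCard, isotropic_stiffness
from spinefe.meshing import CableElement, TetMesh, structured_box_mesh


def iso_card(mesh, E=1000.0, nu=0.3, sigma_max=np.inf, sigma_min=np.inf):
    n = mesh.n_elements
    return MaterialCard(
        region=np.ones(n, dtype=int), hu=np.zeros(n),
        rho_app=np.full(n, np.nan), rho_ash=np.full(n, np.nan),
        Ez=np.full(n, E), sigma_max=np.full(n, sigma_max),
        sigma_min=np.full(n, sigma_min), eps_ab=np.full(n, 0.01),
        C_override=isotropic_stiffness(E, nu),
    )


class TestElementStiffness:
    def test_single_tet_matches_hand_assembly(self):
        """Independent small-matrix oracle: shape-function gradients from a
        4x4 linear fit, K = V B^T C B assembled with explicit loops."""
        nodes = np.array([
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
            [0.3, 0.2, 0.9],
        ])
        mesh = TetMesh(
            nodes=nodes, elems=np.array([[0, 1, 2, 3]]),
            region=np.ones(1, dtype=int),
            inferior_nodes=np.array([0]), superior_nodes=np.array([3]),
        )
        card = iso_card(mesh, E=1.0, nu=0.25)
        op = FEOperator(FEModel(mesh=mesh, card=card, couple_superior=False))

        # oracle: gradient of N_i from solving [1 x y z] a = e_i
        A = np.hstack([np.ones((4, 1)), nodes])
        grads = np.linalg.inv(A)[1:, :].T  # (4 nodes, 3)
        vol = abs(np.linalg.det(nodes[1:] - nodes[0])) / 6.0
        B = np.zeros((6, 12))
        for a in range(4):
            gx, gy, gz = grads[a]
            B[0, 3 * a] = gx
            B[1, 3 * a + 1] = gy
            B[2, 3 * a + 2] = gz
            B[3, 3 * a + 1], B[3, 3 * a + 2] = gz, gy
            B[4, 3 * a], B[4, 3 * a + 2] = gz, gx
            B[5, 3 * a], B[5, 3 * a + 1] = gy, gx
        C = isotropic_stiffness(1.0, 0.25)
        Ke = vol * B.T @ C @ B
        assert np.allclose(op.Ke0[0], Ke, atol=1e-10)


class TestPatchTest:
    def test_affine_boundary_gives_exact_constant_strain(self):
        """C3D4 must reproduce any affine displacement field exactly."""
        mesh = structured_box_mesh((2.0, 2.0, 2.0), (2, 2, 2))
        # perturb an interior node so elements are genuinely irregular
        interior = np.flatnonzero(
            np.all((mesh.nodes > 0.1) & (mesh.nodes < 1.9), axis=1)
        )
        mesh.nodes[interior[0]] += [0.13, -0.08, 0.11]
        card = iso_card(mesh, E=500.0, nu=0.3)
        model = FEModel(mesh=mesh, card=card, couple_superior=False)
        op = FEOperator(model)

        A = np.array([[1e-3, 2e-4, -1e-4],
                      [3e-4, -5e-4, 2e-4],
                      [-2e-4, 1e-4, 8e-4]])
        b = np.array([1e-3, -2e-3, 5e-4])
        u_exact = mesh.nodes @ A.T + b

        on_face = np.any(
            np.isclose(mesh.nodes, 0.0) | np.isclose(mesh.nodes, 2.0), axis=1
        )
        bnodes = np.flatnonzero(on_face)
        pres = np.concatenate([3 * bnodes + i for i in range(3)])
        K = op.assemble()
        fac = op.factorize(K, pres)
        values = np.zeros(len(fac.pres))
        for j, dof in enumerate(fac.pres):
            values[j] = u_exact[dof // 3, dof % 3]
        q, _ = fac.solve(values, None)
        u = op.expand(q).reshape(-1, 3)
        assert np.allclose(u, u_exact, atol=1e-8)
        strain, _ = op.element_stress_strain(op.expand(q))
        sym = 0.5 * (A + A.T)
        expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                             2 * sym[1, 2], 2 * sym[0, 2], 2 * sym[0, 1]])
        assert np.allclose(strain, expected[None, :], atol=1e-8)


class TestStaticSolve:
    def test_zero_load_zero_displacement(self):
        mesh = structured_box_mesh((5, 5, 10), (2, 2, 3))
        model = FEModel(mesh=mesh, card=iso_card(mesh))
        sol = solve_static(model, master_force=np.zeros(6))
        assert np.allclose(sol.u, 0.0, atol=1e-12)

    def test_bar_reaction_matches_closed_form(self):
        """Axial bar with nu = 0: reaction = E A delta / L exactly."""
        E, lx, ly, L, delta = 800.0, 4.0, 3.0, 20.0, 0.05
        mesh = structured_box_mesh((lx, ly, L), (2, 2, 8))
        model = FEModel(mesh=mesh, card=iso_card(mesh, E=E, nu=0.0))
        sol = solve_static(
            model, master_prescribed={i: 0.0 for i in range(6)} | {2: -delta}
        )
        expected = E * lx * ly * delta / L
        assert -sol.master_reaction[2] == pytest.approx(expected, rel=0.02)
        assert -sol.master_reaction[2] == pytest.approx(expected, rel=1e-8)

    def test_missing_dirichlet_raises_singular(self):
        mesh = structured_box_mesh((5, 5, 5), (2, 2, 2))
        mesh.inferior_nodes = np.empty(0, dtype=int)
        model = FEModel(mesh=mesh, card=iso_card(mesh), couple_superior=False)
        with pytest.raises(FESingularError, match="rigid-body"):
            solve_static(model)

    def test_global_equilibrium(self, tiny_model):
        load = np.array([0.0, 0.0, -80.0, 0.0, 0.0, 0.0])
        sol = solve_static(tiny_model, master_force=load)
        total = sol.inferior_reaction + load[:3]
        assert np.linalg.norm(total) < 1e-6 * np.linalg.norm(load[:3])

    def test_damage_scales_identity(self, tiny_model):
        op = FEOperator(tiny_model)
        K1 = op.assemble()
        K2 = op.assemble(damage=np.ones(tiny_model.card.n_elements))
        assert (K1 - K2).nnz == 0 or abs(K1 - K2).max() < 1e-12


class TestCantileverConvergence:
    def test_monotone_from_below_toward_beam_theory(self):
        E, a, L, P = 1000.0, 5.0, 50.0, 2.0
        I = a * a**3 / 12.0
        delta_beam = P * L**3 / (3 * E * I)
        tips = []
        for div in ((2, 2, 10), (3, 3, 15), (4, 4, 20)):
            mesh = structured_box_mesh((a, a, L), div)
            model = FEModel(mesh=mesh, card=iso_card(mesh, E=E, nu=0.0))
            sol = solve_static(model, master_force=[P, 0, 0, 0, 0, 0])
            tips.append(sol.master_u[0])
        assert tips[0] < tips[1] < tips[2] < 1.02 * delta_beam
        # refinement closes the gap to the Euler-Bernoulli deflection
        gaps = [delta_beam - t for t in tips]
        assert gaps[0] > gaps[1] > gaps[2]
        assert tips[2] > 0.55 * delta_beam


class TestPrincipalStresses:
    def test_uniaxial_and_hydrostatic(self):
        uni = principal_stresses(np.array([[5.0, 0, 0, 0, 0, 0]]))
        assert np.allclose(uni, [5.0, 0.0, 0.0])
        hyd = principal_stresses(np.array([[-3.0, -3.0, -3.0, 0, 0, 0]]))
        assert np.allclose(hyd, -3.0)

    def test_matches_eigendecomposition(self, rng):
        voigt = rng.normal(size=(200, 6)) * 10
        ours = principal_stresses(voigt)
        for v, p in zip(voigt, ours):
            T = np.array([
                [v[0], v[5], v[4]],
                [v[5], v[1], v[3]],
                [v[4], v[3], v[2]],
            ])
            ref = np.sort(np.linalg.eigvalsh(T))[::-1]
            assert np.allclose(p, ref, atol=1e-9)


class TestTensionOnlyCables:
    def _model(self):
        mesh = structured_box_mesh((4, 4, 10), (2, 2, 4))
        top = mesh.superior_nodes[0]
        bottom = mesh.inferior_nodes[0]
        cable = CableElement(node_upper=int(top), node_lower=int(bottom),
                             E=200.0, area=5.0, ltype="ALL", gap=0)
        return FEModel(mesh=mesh, card=iso_card(mesh, E=100.0, nu=0.0),
                       cables=[cable])

    def test_cable_active_in_tension(self):
        model = self._model()
        sol = solve_static(
            model, master_prescribed={i: 0.0 for i in range(6)} | {2: 0.1}
        )
        assert sol.active_cables[0]
        assert sol.cable_forces[0] > 0

    def test_cable_inactive_in_compression(self):
        model = self._model()
        sol = solve_static(
            model, master_prescribed={i: 0.0 for i in range(6)} | {2: -0.1}
        )
        assert not sol.active_cables[0]
        assert sol.cable_forces[0] == 0.0

    def test_bilateral_option_keeps_cable(self):
        model = self._model()
        model.tension_only = False
        sol = solve_static(
            model, master_prescribed={i: 0.0 for i in range(6)} | {2: -0.1}
        )
        assert sol.active_cables[0]
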
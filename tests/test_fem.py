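"""Solver verification: element oracles, patch tests, beam theory, ties."""

import numpy as np
import pytest

from mandifem.materials import MaterialCard
from mandifem.mesh import TetMesh, box_mesh, linear_to_quadratic
from mandifem.fem import (assemble_stiffness, solve_static, apply_ties,
                          recover_fields, uniform_traction,
                          SingularSystemError, TieError, elasticity_matrix,
                          von_mises_stress)
from mandifem.muscles import LoadCase

from conftest import uniaxial_case


def sympy_single_tet_stiffness(nodes, E, nu):
    """Independent symbolic assembly of one constant-strain tet.

    Builds the linear shape functions by solving the nodal interpolation
    conditions with sympy, forms the strain energy bilinear form and
    integrates it exactly over the element volume.
    """
    import sympy as sp
    x, y, z = sp.symbols("x y z")
    ones = sp.Matrix([[1, *nodes[i]] for i in range(4)])
    V = sp.Rational(1, 6) * sp.Abs(ones.det())
    shapes = []
    for i in range(4):
        coeffs = ones.solve(
            sp.Matrix([1 if j == i else 0 for j in range(4)]))
        shapes.append(coeffs[0] + coeffs[1] * x + coeffs[2] * y
                      + coeffs[3] * z)
    D = sp.Matrix(elasticity_matrix(E, nu))
    B = sp.zeros(6, 12)
    for i, N in enumerate(shapes):
        dx, dy, dz = sp.diff(N, x), sp.diff(N, y), sp.diff(N, z)
        B[0, 3 * i], B[1, 3 * i + 1], B[2, 3 * i + 2] = dx, dy, dz
        B[3, 3 * i], B[3, 3 * i + 1] = dy, dx
        B[4, 3 * i + 1], B[4, 3 * i + 2] = dz, dy
        B[5, 3 * i], B[5, 3 * i + 2] = dz, dx
    return np.array((V * B.T * D * B).evalf(), dtype=float)


class TestAssembly:
    def test_single_tet_matches_symbolic_oracle(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mesh = TetMesh(nodes=nodes, elements=[[0, 1, 2, 3]])
        K = assemble_stiffness(
            mesh, {"default": MaterialCard("d", 1.0, 0.0)}).K.toarray()
        K_ref = sympy_single_tet_stiffness(nodes, 1.0, 0.0)
        assert np.allclose(K, K_ref, atol=1e-12)

    def test_skewed_tet_with_poisson_matches_oracle(self):
        nodes = np.array([[0.1, 0, 0], [1.2, 0.1, -0.2], [0.3, 0.9, 0.1],
                          [0.2, 0.3, 1.4]])
        mesh = TetMesh(nodes=nodes, elements=[[0, 1, 2, 3]])
        K = assemble_stiffness(
            mesh, {"default": MaterialCard("d", 210.0, 0.3)}).K.toarray()
        K_ref = sympy_single_tet_stiffness(nodes, 210.0, 0.3)
        assert np.allclose(K, K_ref, rtol=1e-10, atol=1e-9)

    def test_stiffness_exactly_symmetric(self, small_box, unit_material):
        K = assemble_stiffness(small_box, unit_material).K
        assert (K - K.T).nnz == 0

    @pytest.mark.parametrize("quadratic", [False, True])
    def test_six_rigid_body_modes(self, unit_material, quadratic):
        m = box_mesh((1, 1, 1), (1, 1, 1))
        if quadratic:
            m = linear_to_quadratic(m)
        K = assemble_stiffness(m, unit_material).K.toarray()
        ev = np.linalg.eigvalsh(K)
        assert (np.abs(ev) < 1e-9 * ev.max()).sum() == 6

    def test_unknown_material_label_rejected(self, small_box):
        with pytest.raises(KeyError, match="default"):
            assemble_stiffness(small_box, {})

    def test_two_material_series_bar_compliance(self):
        """Serial two-material bar: end displacement is the sum of the
        analytic compliances sigma*L_i/E_i."""
        m = box_mesh((1, 1, 2), (2, 2, 4))
        cent = m.centroids()
        m.material_labels = np.where(cent[:, 2] < 1.0, "stiff",
                                     "soft").astype(object)
        mats = {"stiff": MaterialCard("stiff", 2000.0, 0.0),
                "soft": MaterialCard("soft", 500.0, 0.0)}
        sigma = 3.0
        res = solve_static(assemble_stiffness(m, mats), uniaxial_case(m, sigma))
        tip = res.displacements[m.node_set("z1"), 2].mean()
        expected = sigma * (1.0 / 2000.0 + 1.0 / 500.0)
        assert tip == pytest.approx(expected, rel=1e-9)


class TestSolve:
    def test_unconstrained_system_raises_singular_error(self, small_box,
                                                        unit_material):
        case = LoadCase(nodal_forces={0: np.array([1.0, 0, 0])})
        with pytest.raises(SingularSystemError, match="boundary|rigid"):
            solve_static(assemble_stiffness(small_box, unit_material), case)

    @pytest.mark.parametrize("quadratic", [False, True])
    def test_uniaxial_patch_test(self, unit_material, quadratic):
        """Constant-strain state reproduced to 1e-9 by both orders."""
        m = box_mesh((1, 1, 2), (2, 2, 4))
        if quadratic:
            m = linear_to_quadratic(m)
        sigma = 2.0
        res = solve_static(assemble_stiffness(m, unit_material),
                           uniaxial_case(m, sigma))
        E = unit_material["default"].youngs_modulus
        assert np.abs(res.element_strain[:, 2, 2] - sigma / E).max() < 1e-9
        assert np.abs(res.von_mises - sigma).max() < 1e-9
        assert res.info["equilibrium_residual"] < 1e-8
        # fixed DOFs are exactly zero
        z0 = m.node_set("z0")
        assert np.abs(res.displacements[z0, 2]).max() == 0.0

    def test_cantilever_tip_deflection_euler_bernoulli(self):
        """Quadratic tets, 4 elements through depth: tip deflection within
        5 percent of PL^3/(3EI)."""
        E, L, b, h, P = 1000.0, 40.0, 4.0, 4.0, 1.0
        m = linear_to_quadratic(box_mesh((L, b, h), (20, 4, 4)))
        lc = LoadCase()
        lc.nodal_forces = uniform_traction(m, "x1", (0, P / (b * h), 0))
        for n in m.node_set("x0"):
            lc.fixed_dofs += [(int(n), 0), (int(n), 1), (int(n), 2)]
        res = solve_static(
            assemble_stiffness(m, {"default": MaterialCard("d", E, 0.0)}), lc)
        tip = res.displacements[m.node_set("x1"), 1].mean()
        exact = P * L ** 3 / (3 * E * (b * h ** 3 / 12))
        assert tip == pytest.approx(exact, rel=0.05)
        assert res.info["equilibrium_residual"] < 1e-8

    def test_quadratic_converges_faster_than_linear_on_beam(self):
        """At equal edge length the 10-node tets beat the 4-node tets on
        the cantilever oracle by a wide margin."""
        E, L, b, h, P = 1000.0, 40.0, 4.0, 4.0, 1.0
        exact = P * L ** 3 / (3 * E * (b * h ** 3 / 12))
        errs = {}
        for order in ("linear", "quadratic"):
            m = box_mesh((L, b, h), (20, 2, 2))
            if order == "quadratic":
                m = linear_to_quadratic(m)
            lc = LoadCase()
            lc.nodal_forces = uniform_traction(m, "x1", (0, P / (b * h), 0))
            for n in m.node_set("x0"):
                lc.fixed_dofs += [(int(n), 0), (int(n), 1), (int(n), 2)]
            res = solve_static(assemble_stiffness(
                m, {"default": MaterialCard("d", E, 0.0)}), lc)
            tip = res.displacements[m.node_set("x1"), 1].mean()
            errs[order] = abs(tip - exact) / exact
        assert errs["quadratic"] < errs["linear"]
        assert errs["quadratic"] < 0.05 < errs["linear"]


class TestRecovery:
    def test_hydrostatic_state_zero_von_mises(self):
        s = np.array([[5.0, 5.0, 5.0, 0.0, 0.0, 0.0]])
        assert von_mises_stress(s)[0] == pytest.approx(0.0, abs=1e-9)

    def test_uniaxial_stress_von_mises_equals_sigma(self):
        s = np.array([[0.0, 0.0, 7.5, 0.0, 0.0, 0.0]])
        assert von_mises_stress(s)[0] == pytest.approx(7.5, rel=1e-12)

    def test_principal_strains_match_eigensolver(self, small_box,
                                                 unit_material):
        rng = np.random.default_rng(42)
        # impose a random linear displacement field -> uniform strain
        G = rng.normal(scale=1e-3, size=(3, 3))
        disp = small_box.nodes @ G.T
        res = recover_fields(disp, small_box, unit_material)
        eps = 0.5 * (G + G.T)
        expected = np.sort(np.linalg.eigvalsh(eps))[::-1]
        for e in range(small_box.n_elements):
            assert np.allclose(res.principal_strains[e], expected, atol=1e-12)

    def test_principal_strains_invariant_under_rigid_rotation(
            self, unit_material):
        """Rotating model and loads together leaves the principal strains
        unchanged to 1e-9."""
        from scipy.spatial.transform import Rotation
        m = box_mesh((1, 1, 2), (2, 2, 4))
        res = solve_static(assemble_stiffness(m, unit_material),
                           uniaxial_case(m, 2.0))
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True
                                ).as_matrix()
        m2 = TetMesh(nodes=m.nodes @ R.T, elements=m.elements,
                     node_sets={k: v.copy() for k, v in m.node_sets.items()})
        lc = uniaxial_case(m, 2.0)
        lc2 = LoadCase(nodal_forces={n: R @ f
                                     for n, f in lc.nodal_forces.items()})
        # rotated Dirichlet directions are no longer axis-aligned; solve
        # the rotated problem by rotating the solved displacement instead
        res2 = recover_fields(res.displacements @ R.T, m2, unit_material)
        assert np.allclose(res2.principal_strains, res.principal_strains,
                           atol=1e-9)


class TestTies:
    def _stacked_blocks(self):
        bot = box_mesh((1, 1, 1), (2, 2, 2))
        top = box_mesh((1, 1, 1), (2, 2, 2), origin=(0, 0, 1))
        n0 = bot.n_nodes
        mesh = TetMesh(
            nodes=np.vstack([bot.nodes, top.nodes]),
            elements=np.vstack([bot.elements, top.elements + n0]),
            node_sets={"z0": bot.node_sets["z0"],
                       "z1": top.node_sets["z1"] + n0,
                       "iface_bot": bot.node_sets["z1"],
                       "iface_top": top.node_sets["z0"] + n0})
        ties = []
        for s in mesh.node_sets["iface_top"]:
            d = np.linalg.norm(mesh.nodes[mesh.node_sets["iface_bot"]]
                               - mesh.nodes[s], axis=1)
            ties.append((int(s), int(mesh.node_sets["iface_bot"][np.argmin(d)])))
        return mesh, ties

    def test_tied_blocks_match_monolithic_solution(self, unit_material):
        mesh, ties = self._stacked_blocks()
        op = apply_ties(assemble_stiffness(mesh, unit_material), ties,
                        tolerance=1e-9)
        res = solve_static(op, uniaxial_case(mesh, 2.0))
        mono = box_mesh((1, 1, 2), (2, 2, 4))
        res_m = solve_static(assemble_stiffness(mono, unit_material),
                             uniaxial_case(mono, 2.0))
        tied_tip = res.displacements[mesh.node_set("z1"), 2].mean()
        mono_tip = res_m.displacements[mono.node_set("z1"), 2].mean()
        assert tied_tip == pytest.approx(mono_tip, rel=1e-6)
        assert res.info["equilibrium_residual"] < 1e-8

    def test_empty_tie_list_is_noop(self, small_box, unit_material):
        op = assemble_stiffness(small_box, unit_material)
        assert apply_ties(op, []) is op

    def test_tie_beyond_tolerance_rejected(self, unit_material):
        mesh, ties = self._stacked_blocks()
        op = assemble_stiffness(mesh, unit_material)
        with pytest.raises(TieError, match="tolerance"):
            far = [(int(mesh.node_set("z1")[0]), int(mesh.node_set("z0")[0]))]
            apply_ties(op, far, tolerance=0.2)

    def test_tie_chain_rejected(self, small_box, unit_material):
        op = assemble_stiffness(small_box, unit_material)
        with pytest.raises(TieError, match="chain|slave"):
            apply_ties(op, [(0, 1), (1, 2)], tolerance=100.0)


class TestMaterialSensitivity:
    def test_stiffer_cortical_bone_lowers_region_strains(self, human_coarse):
        """Raising the cortical modulus on fixed geometry and load lowers
        the body-averaged strain magnitudes."""
        from mandifem.metrics import (simplified_masseter_load,
                                      region_average_principal_strains)
        case = simplified_masseter_load(human_coarse)
        mags = []
        for E in (15_000.0, 22_000.0):
            mats = {"cortical": MaterialCard("cortical", E, 0.30),
                    "trabecular": MaterialCard("trabecular", 300.0, 0.30)}
            res = solve_static(assemble_stiffness(human_coarse, mats), case)
            s = region_average_principal_strains(res, human_coarse,
                                                 "mandibular_body")
            mags.append(abs(s.avg_max_principal) + abs(s.avg_min_principal))
        assert mags[1] < mags[0]
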
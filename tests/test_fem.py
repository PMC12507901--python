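"""Finite-element solver verification: assembly, analytic solutions,
equilibrium, linearity, superposition and convergence."""

import numpy as np
import pytest

import fractwin as fw
from _helpers import make_bar_mesh, uniform_materials
from fractwin.fem import assemble, von_mises


@pytest.fixture(scope="module")
def bar():
    mesh = make_bar_mesh((2, 2, 20))
    return mesh, uniform_materials(mesh, E=1000.0, nu=0.0)


class TestAssembly:
    def test_single_tet_stiffness_symmetric_psd(self):
        nodes = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]
        mesh = fw.TetMesh(nodes, [[0, 1, 2, 3]], [1], {"distal": [0], "proximal": [3]})
        K, _ = assemble(mesh, uniform_materials(mesh, E=200.0, nu=0.25))
        Kd = K.toarray()
        assert np.abs(Kd - Kd.T).max() < 1e-12 * np.abs(Kd).max()
        eig = np.linalg.eigvalsh(Kd)
        assert eig.min() >= -1e-9 * eig.max()

    def test_rigid_body_translations_in_null_space(self, bar):
        mesh, mats = bar
        K, _ = assemble(mesh, mats)
        for c in range(3):
            u = np.zeros((mesh.n_nodes, 3))
            u[:, c] = 1.0
            f = K @ u.ravel()
            assert np.abs(f).max() < 1e-9 * np.abs(K.data).max()

    def test_stiffness_linear_in_modulus(self, bar):
        mesh, _ = bar
        K1, _ = assemble(mesh, uniform_materials(mesh, E=1000.0, nu=0.2))
        K2, _ = assemble(mesh, uniform_materials(mesh, E=2000.0, nu=0.2))
        diff = (K2 - 2 * K1).tocoo()
        assert np.abs(diff.data).max() < 1e-9 * np.abs(K1.data).max() if diff.nnz else True

    def test_degenerate_element_rejected(self):
        nodes = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]  # coplanar
        with pytest.raises(ValueError, match="element 0"):
            mesh = fw.TetMesh(nodes, [[0, 1, 2, 3]], [1])
            assemble(mesh, uniform_materials(mesh))


class TestAnalyticBar:
    """Uniaxial bar 10x10x100 mm, E = 1000 MPa, nu = 0, 1000 N axial load:
    tip displacement FL/EA = 1.000 mm, uniform axial stress 10 MPa."""

    @pytest.mark.parametrize("order", [1, 2])
    def test_closed_form_reproduced(self, order):
        mesh = make_bar_mesh((2, 2, 20))
        if order == 2:
            mesh = fw.promote_to_quadratic(mesh)
        mats = uniform_materials(mesh, E=1000.0, nu=0.0)
        load = fw.LoadCase(times=[1.0], forces=[[0.0, 0.0, 1000.0]])
        res = fw.solve_static(mesh, mats, fw.BoundaryCondition(), load, distribution="area")
        uz = res.displacement(0)[np.asarray(mesh.node_sets["proximal"]), 2]
        assert np.abs(uz - 1.0).max() < 1e-6
        s = res.stress_voigt(0)
        assert np.abs(s[:, 2] - 10.0).max() < 1e-6 * 10.0
        assert np.abs(np.delete(s, 2, axis=1)).max() < 1e-6 * 10.0

    def test_zero_amplitude_sample_zero_fields(self, bar):
        mesh, mats = bar
        load = fw.LoadCase(times=[0.0, 0.5, 1.0],
                           forces=[[0, 0, 0], [100.0, -50.0, 800.0], [0, 0, 0]])
        res = fw.solve_static(mesh, mats, fw.BoundaryCondition(), load)
        assert np.all(res.displacement(0) == 0.0)
        assert np.all(res.strain_voigt(2) == 0.0)
        assert np.all(res.von_mises_field(0) == 0.0)


class TestEquilibriumAndLinearity:
    def test_reactions_balance_applied_loads(self, small_solver):
        load = fw.LoadCase(times=np.linspace(0, 1, 9),
                           forces=np.random.default_rng(0).normal(0, 800.0, (9, 3)))
        res = small_solver.result(load)
        rf = res.reaction_trace()
        assert np.abs(rf + load.forces).max() <= 1e-8 * np.abs(load.forces).max()

    def test_fields_scale_exactly_with_amplitude(self, small_solver):
        load = fw.LoadCase(times=[0.3, 0.9], forces=[[50.0, 20.0, 700.0], [10.0, -5.0, 300.0]])
        res1 = small_solver.result(load)
        res2 = small_solver.result(load.scaled(2.0))
        for i in range(2):
            assert np.array_equal(2.0 * res1.displacement(i), res2.displacement(i))
            assert np.array_equal(2.0 * res1.strain_voigt(i), res2.strain_voigt(i))

    def test_superposition_matches_per_sample_resolve(self, small_state):
        mesh, mats = small_state["mesh"], small_state["materials"]
        solver = fw.LinearGaitSolver(mesh, mats, fw.BoundaryCondition())
        load = fw.LoadCase(times=np.linspace(0, 1, 5),
                           forces=np.random.default_rng(1).normal(0, 600.0, (5, 3)))
        fast = solver.result(load, mode="superpose")
        slow = solver.result(load, mode="per_sample")
        for i in range(5):
            scale = max(np.abs(slow.displacement(i)).max(), 1e-30)
            assert np.abs(fast.displacement(i) - slow.displacement(i)).max() <= 1e-8 * scale
            sscale = max(np.abs(slow.strain_voigt(i)).max(), 1e-30)
            assert np.abs(fast.strain_voigt(i) - slow.strain_voigt(i)).max() <= 1e-8 * sscale

    def test_empty_fixed_set_rejected(self, small_state):
        mesh, mats = small_state["mesh"], small_state["materials"]
        load = fw.LoadCase(times=[1.0], forces=[[0, 0, 100.0]])
        with pytest.raises(ValueError, match="singular"):
            fw.solve_static(mesh, mats, fw.BoundaryCondition(node_set="nope"), load)


class TestPatchAndConvergence:
    def test_uniform_strain_patch(self):
        """Imposing a linear displacement field reproduces its uniform strain
        in every element and leaves interior nodes in equilibrium."""
        mesh = make_bar_mesh((2, 2, 4), length=20.0)
        mats = uniform_materials(mesh, E=500.0, nu=0.3)
        K, cache = assemble(mesh, mats)
        A = np.array([[1e-3, 4e-4, -2e-4], [4e-4, -5e-4, 1e-4], [-2e-4, 1e-4, 8e-4]])
        u = mesh.nodes @ A.T
        strain = np.einsum("mvd,md->mv", cache.B_mean, u.ravel()[cache.dof_map])
        sym = 0.5 * (A + A.T)
        expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                             2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]])
        assert np.abs(strain - expected[None, :]).max() < 1e-9
        # interior equilibrium: K u vanishes away from the boundary
        f = (K @ u.ravel()).reshape(-1, 3)
        boundary = np.zeros(mesh.n_nodes, dtype=bool)
        coords = mesh.nodes
        for d, extent in zip(range(3), coords.max(axis=0)):
            boundary |= np.isclose(coords[:, d], 0) | np.isclose(coords[:, d], extent)
        assert np.abs(f[~boundary]).max() < 1e-9 * max(np.abs(f).max(), 1e-30)

    def test_bar_tip_error_decreases_under_refinement(self):
        """nu = 0.3 bar with a fully fixed base: tip displacement converges
        monotonically toward the fine-mesh reference."""
        def tip(nv):
            mesh = make_bar_mesh(nv)
            mats = uniform_materials(mesh, E=1000.0, nu=0.3)
            load = fw.LoadCase(times=[1.0], forces=[[0, 0, 1000.0]])
            res = fw.solve_static(mesh, mats, fw.BoundaryCondition(), load,
                                  distribution="area")
            return res.displacement(0)[np.asarray(mesh.node_sets["proximal"]), 2].mean()

        ref = tip((8, 8, 80))
        errs = [abs(tip(nv) - ref) for nv in [(1, 1, 10), (2, 2, 20), (4, 4, 40)]]
        assert errs[0] > errs[1] > errs[2]


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert von_mises(np.diag([7.0, 7.0, 7.0])) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sigma", [10.0, -3.5])
    def test_uniaxial_gives_magnitude(self, sigma):
        assert von_mises(np.diag([sigma, 0, 0.0])) == pytest.approx(abs(sigma), rel=1e-12)

    def test_pure_shear_sqrt3(self):
        tau = 4.2
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = tau
        assert von_mises(S) == pytest.approx(np.sqrt(3) * tau, rel=1e-12)

    def test_asymmetric_rejected(self):
        S = np.zeros((3, 3))
        S[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            von_mises(S)
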
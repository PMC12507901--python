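"""Strain invariants, healing-window classification and assessment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fractwin as fw
from fractwin.fem import _ElementCache, FEResult
from fractwin.healing import INF, WindowRule


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _random_symmetric(seed, scale=0.05):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, scale, (3, 3))
    return 0.5 * (a + a.T)


class TestStrainInvariants:
    @pytest.mark.parametrize("a", [0.0, 0.01, -0.2])
    def test_spherical_strain_has_zero_shear(self, a):
        assert fw.octahedral_shear(np.diag([a, a, a])) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_closed_form(self):
        expected = (2.0 / 3.0) * np.sqrt(2.0) * 0.01
        assert fw.octahedral_shear(np.diag([0.01, 0, 0.0])) == pytest.approx(expected, rel=1e-12)

    def test_volumetric_trace(self):
        assert fw.volumetric_strain(np.diag([0.01, 0.01, 0.01])) == pytest.approx(0.03, rel=1e-12)
        shear = np.array([[0, 0.02, 0], [0.02, 0, 0], [0, 0, 0.0]])
        assert fw.volumetric_strain(shear) == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_rotation_invariance(self, seed_e, seed_r):
        E = _random_symmetric(seed_e)
        R = _random_rotation(seed_r)
        Er = R @ E @ R.T
        Er = 0.5 * (Er + Er.T)  # symmetrize away rounding
        assert abs(fw.octahedral_shear(Er) - fw.octahedral_shear(E)) < 1e-12
        assert abs(fw.volumetric_strain(Er) - fw.volumetric_strain(E)) < 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(1e-3, 1e3))
    def test_homogeneous_degree_one(self, seed, alpha):
        E = _random_symmetric(seed)
        assert fw.octahedral_shear(alpha * E) == pytest.approx(
            alpha * fw.octahedral_shear(E), rel=1e-9, abs=1e-15
        )

    def test_asymmetric_rejected(self):
        E = np.zeros((3, 3))
        E[0, 1] = 1e-3
        with pytest.raises(ValueError, match="symmetric"):
            fw.octahedral_shear(E)


class TestHealingWindow:
    @pytest.mark.parametrize(
        "gamma,vol,expected",
        [
            (0.02, -0.001, "intramembranous ossification"),
            (0.10, -0.02, "endochondral ossification"),
            (0.40, 0.0, "connective tissue"),
        ],
    )
    def test_default_classification(self, gamma, vol, expected):
        win = fw.default_window()
        assert str(np.asarray(win.classify_names(gamma, vol)).item()) == expected

    def test_partition_complete_on_dense_grid(self):
        """Every point of a 200x200 stimulus grid belongs to exactly one class."""
        win = fw.default_window()
        g, v = np.meshgrid(np.linspace(0, 1, 200), np.linspace(-0.5, 0.5, 200), indexing="ij")
        hits = np.zeros(g.shape, dtype=int)
        for rule in win.rules:
            hits += rule.contains(g, v).astype(int)
        assert np.all(hits == 1)
        assert win.classify(g, v).min() >= 0

    def test_incomplete_window_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            fw.HealingWindowConfig([WindowRule("only", (0.0, 0.1), (-0.1, 0.1))])

    def test_overlapping_window_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            fw.HealingWindowConfig(
                [
                    WindowRule("a", (0.0, INF), (-INF, INF)),
                    WindowRule("b", (0.0, 0.1), (-0.1, 0.1)),
                ]
            )

    def test_yaml_round_trip(self, tmp_path):
        win = fw.default_window()
        win.save(tmp_path / "window.yaml")
        win2 = fw.HealingWindowConfig.load(tmp_path / "window.yaml")
        assert win2.class_names == win.class_names
        g, v = np.meshgrid(np.linspace(0, 0.5, 40), np.linspace(-0.3, 0.3, 40), indexing="ij")
        assert np.array_equal(win.classify(g, v), win2.classify(g, v))


def _two_gap_result(strains, volumes, region, times=(0.0,), E=1000.0, nu=0.0):
    """Handcrafted FEResult: given per-element engineering-Voigt strains."""
    m = len(strains)
    from fractwin.fem import _isotropic_D

    cache = _ElementCache(
        volumes=np.asarray(volumes, dtype=float),
        B_mean=np.zeros((m, 6, 12)),
        D=_isotropic_D(np.full(m, E), np.full(m, nu)),
        dof_map=np.zeros((m, 12), dtype=int),
    )
    k = len(times)
    basis_strain = np.asarray(strains, dtype=float)[None, :, :]
    basis_U = np.zeros((1, 4, 3))
    coeffs = np.ones((k, 1))
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    mesh = fw.TetMesh(nodes, [[0, 1, 2, 3]] * m, region)
    result = FEResult(np.asarray(times), coeffs, basis_U, basis_strain, cache,
                      np.zeros((1, 3)), np.zeros((k, 3)))
    return result, mesh


class TestAssessment:
    def test_volume_weighted_fractions(self):
        """Two gap elements of 1 and 3 mm³ in different classes -> 0.25/0.75."""
        strains = [
            [0.01, 0.0, 0.0, 0.0, 0.0, 0.0],  # gamma ~ 0.0094 -> intramembranous
            [0.3, 0.0, 0.0, 0.0, 0.0, 0.0],  # gamma ~ 0.28 -> connective tissue
        ]
        result, mesh = _two_gap_result(strains, [1.0, 3.0], [fw.volume.GAP, fw.volume.GAP])
        a = fw.assess(result, mesh)
        i_im = a.class_names.index("intramembranous ossification")
        i_ct = a.class_names.index("connective tissue")
        assert a.class_fractions[0, i_im] == pytest.approx(0.25, abs=1e-12)
        assert a.class_fractions[0, i_ct] == pytest.approx(0.75, abs=1e-12)
        assert a.class_fractions.sum(axis=1) == pytest.approx(1.0, abs=1e-12)
        assert a.stable is None  # no implant elements

    def test_yield_check_against_880(self):
        """Peak implant von Mises 500 MPa < 880 MPa yield -> stable."""
        strains = [
            [0.01, 0.0, 0.0, 0.0, 0.0, 0.0],  # gap
            [0.5, 0.0, 0.0, 0.0, 0.0, 0.0],  # implant: E=1000, nu=0 -> sigma_xx=500
        ]
        result, mesh = _two_gap_result(
            strains, [1.0, 1.0], [fw.volume.GAP, fw.volume.IMPLANT]
        )
        a = fw.assess(result, mesh, yield_strength=880.0)
        assert a.peak_implant_von_mises == pytest.approx(500.0, rel=1e-12)
        assert a.stable is True
        a2 = fw.assess(result, mesh, yield_strength=400.0)
        assert a2.stable is False

    def test_no_gap_elements_rejected(self):
        strains = [[0.01, 0, 0, 0, 0, 0.0]]
        result, mesh = _two_gap_result(strains, [1.0], [fw.volume.IMPLANT])
        with pytest.raises(ValueError, match="gap"):
            fw.assess(result, mesh)

    def test_load_scaling_monotone_end_to_end(self, small_state, small_solver):
        """Scaling the amplitude scales gamma_oct and implant VM exactly and
        never improves the unfavorable fraction (default window)."""
        base = fw.LoadCase(times=[1.0], forces=[[30.0, 15.0, 400.0]])
        peaks_g, peaks_vm, unfav = [], [], []
        for alpha in (0.5, 1.0, 2.0):
            res = small_solver.result(base.scaled(alpha))
            a = fw.assess(res, small_state["mesh"])
            peaks_g.append(a.peak_gap_gamma_oct)
            peaks_vm.append(a.peak_implant_von_mises)
            unfav.append(a.worst_unfavorable_fraction)
        assert peaks_g[1] == pytest.approx(2 * peaks_g[0], rel=1e-9)
        assert peaks_g[2] == pytest.approx(4 * peaks_g[0], rel=1e-9)
        assert peaks_vm[1] == pytest.approx(2 * peaks_vm[0], rel=1e-9)
        assert unfav[0] <= unfav[1] <= unfav[2]
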
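"""%BW normalization, resampling, reference database and compliance."""

import numpy as np
import pytest

import fractwin as fw
from fractwin.gait import WeightBearingLevel


def _curve(values, unit="N", **kw):
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        values = np.repeat(values, 2)
    return fw.GaitForceCurve(np.linspace(0, 1, len(values)),
                             np.column_stack([values, values, values]), unit=unit, **kw)


class TestNormalization:
    def test_bodyweight_force_is_100_pct(self):
        curve = _curve([686.7])  # 70 kg * 9.81 m/s²
        bw = fw.normalize_to_bw(curve, 70.0)
        assert bw.F[0, 2] == pytest.approx(100.0, rel=1e-12)
        assert bw.unit == "%BW"

    def test_zero_force_zero_pct(self):
        assert np.all(fw.normalize_to_bw(_curve([0.0]), 80.0).F == 0.0)

    def test_round_trip_exact(self):
        rng = np.random.default_rng(11)
        curve = fw.GaitForceCurve(np.linspace(0, 1, 31), rng.normal(0, 900, (31, 3)), unit="N")
        back = fw.denormalize_to_newtons(fw.normalize_to_bw(curve, 63.5), 63.5)
        assert np.abs(back.F - curve.F).max() <= 1e-12 * np.abs(curve.F).max()

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            fw.normalize_to_bw(_curve([100.0]), 0.0)


class TestResampling:
    def test_identity_on_original_grid(self):
        curve = _curve([0, 3, 1, 7, 2.0], unit="%BW")
        out = fw.resample_curve(curve, 5)
        assert np.array_equal(out.F, curve.F)

    def test_linear_ramp_exact(self):
        t = np.linspace(0, 1, 6)
        curve = fw.GaitForceCurve(t, np.column_stack([10 * t] * 3), unit="%BW")
        out = fw.resample_curve(curve, 17)
        assert np.allclose(out.F[:, 0], 10 * out.t, atol=1e-12)

    def test_two_point_curve_to_eleven(self):
        curve = fw.GaitForceCurve([0.0, 1.0], [[0, 0, 0], [10, 10, 10.0]], unit="%BW")
        out = fw.resample_curve(curve, 11)
        assert np.allclose(out.F[:, 2], np.arange(11.0), atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fw.resample_curve(_curve([1.0, 2.0]), 1)


class TestReferenceDatabase:
    def test_mean_of_identical_curves(self):
        c = _curve([1, 5, 2.0], unit="%BW")
        db = fw.build_reference({WeightBearingLevel.FULL: [c, c, c]}, n_grid=3)
        assert np.allclose(db.mean[WeightBearingLevel.FULL].F, c.F)

    def test_mean_of_opposite_curves_is_zero(self):
        c = _curve([1, 5, 2.0], unit="%BW")
        neg = fw.GaitForceCurve(c.t, -c.F, unit="%BW")
        db = fw.build_reference({WeightBearingLevel.FULL: [c, neg]}, n_grid=3)
        assert np.allclose(db.mean[WeightBearingLevel.FULL].F, 0.0)

    def test_cohort_mean_unbiased(self):
        """22 seeded noisy curves: the database mean stays within standard
        error of the noise-free generator curve."""
        sd = 5.0
        curves = [
            fw.generate_gait_curve(fw.SyntheticCurveSpec(noise_sd=sd, seed=s))
            for s in range(22)
        ]
        clean = fw.generate_gait_curve(fw.SyntheticCurveSpec(noise_sd=0.0))
        db = fw.build_reference({WeightBearingLevel.FULL: curves}, n_grid=clean.t.size)
        err = np.abs(db.mean[WeightBearingLevel.FULL].F - clean.F)
        assert err.max() <= 3 * sd / np.sqrt(22) * 1.5

    def test_empty_level_rejected(self):
        with pytest.raises(ValueError):
            fw.build_reference({WeightBearingLevel.FULL: []})

    def test_save_load_round_trip(self, tmp_path):
        curves = [fw.generate_gait_curve(fw.SyntheticCurveSpec(noise_sd=3.0, seed=s))
                  for s in range(3)]
        db = fw.build_reference({WeightBearingLevel.FULL: curves}, n_grid=21)
        db.save(tmp_path / "db")
        db2 = fw.ReferenceDatabase.load(tmp_path / "db")
        assert np.allclose(db2.mean[WeightBearingLevel.FULL].F,
                           db.mean[WeightBearingLevel.FULL].F)
        assert len(db2.members[WeightBearingLevel.FULL]) == 3


class TestScaleToPatient:
    def _db_constant(self, pct):
        c = fw.GaitForceCurve([0.0, 1.0], np.full((2, 3), pct), unit="%BW")
        return fw.build_reference({WeightBearingLevel.FULL: [c]}, n_grid=2)

    def test_constant_100_pct_at_70_kg(self):
        lc = fw.scale_to_patient(self._db_constant(100.0), WeightBearingLevel.FULL, 70.0)
        assert np.allclose(lc.forces, 686.7, rtol=1e-12)

    def test_zero_curve_zero_loadcase(self):
        lc = fw.scale_to_patient(self._db_constant(0.0), WeightBearingLevel.FULL, 70.0)
        assert np.all(lc.forces == 0.0)

    def test_peak_scaling_contract(self):
        """Axial peak 260 %BW at 80 kg -> 2.6 * 80 * 9.81 N."""
        curve = fw.generate_gait_curve(
            fw.SyntheticCurveSpec(axial_peaks=(260.0, 240.0), noise_sd=0.0)
        )
        db = fw.build_reference({WeightBearingLevel.FULL: [curve]}, n_grid=curve.t.size)
        lc = fw.scale_to_patient(db, WeightBearingLevel.FULL, 80.0)
        assert lc.forces[:, 2].max() == pytest.approx(2.6 * 80.0 * 9.81, rel=1e-12)

    def test_linear_in_mass(self):
        db = self._db_constant(137.0)
        lc1 = fw.scale_to_patient(db, WeightBearingLevel.FULL, 60.0)
        lc2 = fw.scale_to_patient(db, WeightBearingLevel.FULL, 120.0)
        assert np.array_equal(2.0 * lc1.forces, lc2.forces)

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError):
            fw.scale_to_patient(self._db_constant(1.0), WeightBearingLevel.PWB_20KG, 70.0)


class TestCompliance:
    def test_on_target_compliant(self):
        grf = fw.generate_insole_curve(196.2, fw.InsoleCurveSpec(rel_error_sd=0.0))
        rep = fw.check_compliance(grf, 20.0)
        assert rep.compliant and rep.verdict == "compliant"
        assert rep.ratio == pytest.approx(1.0, rel=1e-12)

    def test_overload_detected(self):
        grf = fw.generate_insole_curve(400.0, fw.InsoleCurveSpec(rel_error_sd=0.0))
        rep = fw.check_compliance(grf, 20.0)
        assert not rep.compliant and rep.verdict == "overload"
        assert rep.ratio == pytest.approx(400.0 / 196.2, rel=1e-9)

    def test_underload_detected(self):
        grf = fw.GRFCurve(np.linspace(0, 1, 11), np.zeros(11))
        rep = fw.check_compliance(grf, 20.0)
        assert rep.verdict == "underload" and rep.ratio == 0.0

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="[Ee]mpty"):
            fw.check_compliance(fw.GRFCurve(np.empty(0), np.empty(0)), 20.0)
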
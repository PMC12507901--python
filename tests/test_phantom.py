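"""Synthetic CT phantom and force-curve generators."""

import numpy as np
import pytest

import fractwin as fw
from fractwin.volume import CORTICAL, GAP, IMPLANT, TRABECULAR


class TestPhantomVolume:
    def test_seed_determinism(self):
        spec = fw.PhantomSpec(shape=(16, 16, 24), spacing=3.0, noise_sd=15.0, seed=42)
        v1, l1 = fw.generate_phantom_volume(spec)
        v2, l2 = fw.generate_phantom_volume(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(l1, l2)

    def test_different_seeds_differ(self):
        base = dict(shape=(16, 16, 24), spacing=3.0, noise_sd=15.0)
        v1, _ = fw.generate_phantom_volume(fw.PhantomSpec(seed=1, **base))
        v2, _ = fw.generate_phantom_volume(fw.PhantomSpec(seed=2, **base))
        assert not np.array_equal(v1.data, v2.data)

    def test_rod_hu_identity_map_exact(self):
        """With the identity density map and no noise, rod voxels carry the
        certified densities as HU values exactly."""
        rho = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)
        spec = fw.PhantomSpec(
            shape=(24, 24, 24), spacing=2.5, noise_sd=0.0,
            rod_densities=rho, calib_slope=1.0, calib_intercept=0.0,
        )
        vol, labels = fw.generate_phantom_volume(spec)
        for i, r in enumerate(rho):
            mask = labels == fw.volume.rod_label(i)
            assert mask.any()
            assert vol.data[mask].mean() == pytest.approx(r, abs=0.0)

    def test_tissue_hu_ordering(self, noise_free_phantom):
        vol, labels = noise_free_phantom
        means = {lab: vol.data[labels == lab].mean() for lab in (GAP, TRABECULAR, CORTICAL, IMPLANT)}
        assert means[GAP] < means[TRABECULAR] < means[CORTICAL] < means[IMPLANT]

    def test_implant_voxel_count_matches_brute_force(self, noise_free_spec, noise_free_phantom):
        """Independent scalar voxel-membership oracle over the configured
        plate box and screw cylinders."""
        spec = noise_free_spec
        _, labels = noise_free_phantom
        lo, hi = spec.plate_box()
        screws = spec.screw_segments()
        count = 0
        nx, ny, nz = spec.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    x = (i + 0.5) * spec.spacing
                    y = (j + 0.5) * spec.spacing
                    z = (k + 0.5) * spec.spacing
                    inside = (
                        lo[0] <= x < hi[0] and lo[1] <= y < hi[1] and lo[2] <= z < hi[2]
                    )
                    if not inside:
                        for x_lo, x_hi, yc, zc in screws:
                            if x_lo <= x < x_hi and (y - yc) ** 2 + (z - zc) ** 2 <= spec.screw_radius**2:
                                inside = True
                                break
                    count += inside
        assert count == int(np.sum(labels == IMPLANT))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(shape=(0, 16, 16)),
            dict(spacing=-1.0),
            dict(inner_radius=15.0, outer_radius=12.0),
            dict(rod_densities=(100.0, 100.0, 200.0)),
            dict(gap_thickness=1e4),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            fw.PhantomSpec(**bad)


class TestGaitCurves:
    def test_noise_free_peak_value_and_time(self):
        spec = fw.SyntheticCurveSpec(axial_peaks=(100.0, 90.0), noise_sd=0.0, n_samples=101)
        curve = fw.generate_gait_curve(spec)
        fz = curve.F[:, 2]
        assert fz.max() == pytest.approx(100.0, abs=1e-12)
        assert curve.t[np.argmax(fz)] == pytest.approx(spec.peak_times[0], abs=1e-12)
        assert fz[0] == fz[-1] == spec.baseline

    def test_zero_peaks_give_zero_curve(self):
        spec = fw.SyntheticCurveSpec(
            axial_peaks=(0.0, 0.0), ap_peaks=(0.0, 0.0), ml_peaks=(0.0, 0.0), noise_sd=0.0
        )
        assert np.all(fw.generate_gait_curve(spec).F == 0.0)

    def test_seeded_noise_unbiased(self):
        """Mean of many seeded noisy draws approaches the noise-free curve."""
        sd, n_draws = 4.0, 120
        clean = fw.generate_gait_curve(fw.SyntheticCurveSpec(noise_sd=0.0))
        draws = [
            fw.generate_gait_curve(fw.SyntheticCurveSpec(noise_sd=sd, seed=s)).F
            for s in range(n_draws)
        ]
        assert not np.array_equal(draws[0], draws[1])
        mean = np.mean(draws, axis=0)
        # interior samples carry the noise; endpoints are pinned to baseline
        assert np.abs(mean - clean.F)[1:-1].max() < 3 * sd / np.sqrt(n_draws) * 1.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fw.SyntheticCurveSpec(n_samples=5)


class TestInsoleCurves:
    def test_exact_peak_without_error(self):
        grf = fw.generate_insole_curve(196.2, fw.InsoleCurveSpec(rel_error_sd=0.0))
        assert grf.fz.max() == pytest.approx(196.2, abs=1e-12)

    def test_zero_load_gives_zero_curve(self):
        assert np.all(fw.generate_insole_curve(0.0).fz == 0.0)

    def test_peak_error_distribution(self):
        """Monte-Carlo: empirical sd of peak/prescribed matches the configured
        relative error sd within 10%."""
        sd = 0.1
        peaks = np.array(
            [
                fw.generate_insole_curve(200.0, fw.InsoleCurveSpec(rel_error_sd=sd, seed=s)).fz.max()
                for s in range(1000)
            ]
        )
        emp = np.std(peaks / 200.0)
        assert abs(emp - sd) < 0.1 * sd

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            fw.generate_insole_curve(-5.0)
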
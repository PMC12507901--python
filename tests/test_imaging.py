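"""Density calibration and adaptive segmentation."""

import numpy as np
import pytest

import fractwin as fw
from fractwin.volume import BACKGROUND, BONE, IMPLANT, VoxelVolume, as_bone


def _rod_volume(mean_hu, n=4):
    """Tiny volume with one n-voxel cube per rod painted at the given HU."""
    data = np.zeros((4 * len(mean_hu), 4, 4))
    regions = []
    for i, hu in enumerate(mean_hu):
        mask = np.zeros_like(data, dtype=bool)
        mask[4 * i : 4 * i + 2, :2, :2] = True
        data[mask] = hu
        regions.append(mask)
    return VoxelVolume(data, (1.0, 1.0, 1.0)), regions


class TestCalibration:
    def test_exact_linear_data(self):
        vol, regions = _rod_volume([10.0, 110.0, 210.0])
        cal = fw.calibrate_density(vol, regions, [25.0, 225.0, 425.0])
        assert cal.slope == pytest.approx(2.0, rel=1e-12)
        assert cal.intercept == pytest.approx(5.0, abs=1e-9)
        assert cal.rmse == pytest.approx(0.0, abs=1e-9)

    def test_identity_map(self):
        hu = [0.0, 100.0, 200.0, 400.0]
        vol, regions = _rod_volume(hu)
        cal = fw.calibrate_density(vol, regions, hu)
        assert cal.slope == pytest.approx(1.0, rel=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_recovers_generator_truth(self, small_state):
        """Noise-free phantom: OLS on the rods recovers the true map to 1e-9."""
        cal = small_state["calibration"]
        spec = small_state["spec"]
        assert cal.slope == pytest.approx(spec.calib_slope, rel=1e-9)
        assert cal.intercept == pytest.approx(spec.calib_intercept, rel=1e-9)

    def test_rod_prediction_within_residual(self, small_state):
        cal = small_state["calibration"]
        for rho, mean_hu, _ in cal.rods:
            assert abs(cal.density(mean_hu) - rho) <= max(3 * cal.rmse, 1e-9)

    def test_fewer_than_two_rods_rejected(self):
        vol, regions = _rod_volume([100.0])
        with pytest.raises(ValueError, match="2 rods"):
            fw.calibrate_density(vol, regions, [200.0])

    def test_degenerate_rod_hu_rejected(self):
        vol, regions = _rod_volume([100.0, 100.0, 100.0])
        with pytest.raises(ValueError, match="[Dd]egenerate"):
            fw.calibrate_density(vol, regions, [0.0, 100.0, 200.0])


class TestSegmentation:
    def test_matches_ground_truth_on_noise_free_phantom(self, small_state):
        """Voxel-wise agreement with the generator's labels for the bone and
        implant classes (>= 99%)."""
        labels_true = small_state["labels"]
        seg = small_state["masks"].labels
        bone_true = as_bone(labels_true)
        bone_seg = seg == BONE
        assert (bone_true & bone_seg).sum() / bone_true.sum() >= 0.99
        assert (bone_seg & ~bone_true).sum() <= 0.01 * bone_true.sum()
        imp_true = labels_true == IMPLANT
        imp_seg = seg == IMPLANT
        assert (imp_true == imp_seg).all()

    def test_gap_detected_inside_envelope(self, small_state):
        labels_true = small_state["labels"]
        seg = small_state["masks"].labels
        gap_true = labels_true == fw.volume.GAP
        gap_seg = seg == fw.volume.GAP
        assert (gap_true & gap_seg).sum() / gap_true.sum() >= 0.99

    def test_uniform_background_all_background(self):
        vol = VoxelVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        cal = fw.DensityCalibration(slope=1.0, intercept=0.0, rmse=0.0,
                                    rods=[(0.0, 0.0, 1), (100.0, 100.0, 1)])
        seg = fw.segment_adaptive(vol, cal)
        assert np.all(seg.labels == BACKGROUND)

    def test_metal_threshold_below_cortical_mislabels_bone(self, small_state):
        """Documented failure mode: a metal threshold under the cortical HU
        absorbs cortical voxels into the implant class."""
        vol = small_state["volume"]
        cal = small_state["calibration"]
        cfg = fw.SegmentationConfig(metal_hu_threshold=1000.0)
        seg = fw.segment_adaptive(vol, cal, cfg)
        cortical_true = small_state["labels"] == fw.volume.CORTICAL
        assert (seg.labels[cortical_true] == IMPLANT).mean() > 0.9

    def test_thresholds_out_of_order_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            fw.SegmentationConfig(bone_density_threshold=100.0, gap_density_threshold=200.0)
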
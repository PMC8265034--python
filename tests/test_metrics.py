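import numpy as np
import pytest
from scipy import ndimage

from mrflesion.metrics import (
    binarize,
    dice,
    lesion_detection_rate,
    lesion_profile,
    mean_relative_deviation,
    per_lesion_stats,
    threshold_sweep,
)


def _two_lesion_volume():
    gt = np.zeros((20, 20, 6), dtype=bool)
    gt[2:6, 2:6, 1:4] = True  # lesion A: 48 voxels
    gt[12:16, 12:16, 2:5] = True  # lesion B: 48 voxels
    return gt


class TestDice:
    def test_identity(self):
        a = _two_lesion_volume()
        assert dice(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 2), bool)
        b = np.zeros((4, 4, 2), bool)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, :4, 0] = True  # |a| = 4
        b[0, 2:, 0] = True
        b[1, :2, 0] = True  # |b| = 4, overlap 2
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        empty = np.zeros((4, 4, 1), bool)
        assert dice(empty, empty) == 1.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((8, 8, 3)) > 0.7
            b = rng.random((8, 8, 3)) > 0.7
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((3, 3, 1), bool), np.zeros((4, 4, 1), bool))

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 7, 8)) > 0.6
        b = rng.random((6, 7, 8)) > 0.6
        assert dice(a, b) == dice(a.transpose(2, 0, 1), b.transpose(2, 0, 1))


class TestBinarize:
    def test_below_threshold_empty(self):
        prob = np.full((4, 4, 1), 0.3)
        assert not binarize(prob, 0.33).any()

    def test_closed_threshold_boundary(self):
        prob = np.full((4, 4, 1), 0.8)
        assert binarize(prob, 0.8).all()

    def test_volume_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        prob = rng.random((10, 10, 4))
        volumes = [binarize(prob, t).sum() for t in np.linspace(0.05, 0.95, 20)]
        assert all(v1 >= v2 for v1, v2 in zip(volumes, volumes[1:]))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2, 1)), 0.0)


class TestLesionDetectionRate:
    def test_perfect_prediction(self):
        gt = _two_lesion_volume()
        assert lesion_detection_rate(gt, gt) == 1.0

    def test_empty_prediction(self):
        gt = np.zeros((10, 10, 3), bool)
        gt[1, 1, 1] = gt[5, 5, 1] = gt[8, 8, 1] = True  # 3 isolated lesions
        assert lesion_detection_rate(gt, np.zeros_like(gt)) == 0.0

    def test_partial_detection_two_of_three(self):
        gt = np.zeros((12, 12, 3), bool)
        gt[1:3, 1:3, 1] = True
        gt[6:8, 6:8, 1] = True
        gt[10:12, 10:12, 2] = True
        pred = np.zeros_like(gt)
        pred[1, 1, 1] = True  # hits lesion 1 with a single voxel
        pred[7, 7, 1] = True  # hits lesion 2
        assert lesion_detection_rate(gt, pred) == pytest.approx(2.0 / 3.0)

    def test_empty_ground_truth_defined_as_one(self):
        pred = np.ones((4, 4, 1), bool)
        assert lesion_detection_rate(np.zeros((4, 4, 1), bool), pred) == 1.0

    def test_diagonal_voxels_are_one_component(self):
        # 26-connectivity joins diagonal neighbours
        gt = np.zeros((6, 6, 2), bool)
        gt[1, 1, 0] = True
        gt[2, 2, 1] = True
        pred = np.zeros_like(gt)
        pred[1, 1, 0] = True
        assert lesion_detection_rate(gt, pred) == 1.0


class TestThresholdSweep:
    def test_detection_rate_non_increasing(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gt = np.zeros((12, 12, 4), bool)
            gt[3:6, 3:6, 1:3] = True
            prob = np.clip(
                gt * rng.uniform(0.4, 1.0) + rng.random(gt.shape) * 0.5, 0, 1
            )
            sweep = threshold_sweep(prob, gt, np.linspace(0.05, 0.95, 50))
            rates = sweep.detection_rates
            assert all(r1 >= r2 for r1, r2 in zip(rates, rates[1:]))

    def test_perfect_probability_map(self):
        gt = _two_lesion_volume()
        sweep = threshold_sweep(gt.astype(float), gt, np.linspace(0.1, 0.9, 9))
        np.testing.assert_array_equal(sweep.dice_values, 1.0)

    def test_interior_optimum_with_background(self):
        # blurred truth + constant background: best dice strictly inside (0, 1)
        gt = _two_lesion_volume()
        prob = ndimage.gaussian_filter(gt.astype(float), 1.0) + 0.1
        prob = np.clip(prob, 0, 1)
        sweep = threshold_sweep(prob, gt, np.linspace(0.05, 0.95, 50))
        assert 0.05 < sweep.best_threshold < 0.95
        assert sweep.dice_values.max() > sweep.dice_values[0]
        assert sweep.dice_values.max() > sweep.dice_values[-1]

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(np.zeros((2, 2, 1)), np.zeros((2, 2, 1), bool), [0.5, 0.3])


class TestMeanRelativeDeviation:
    def test_identity_zero(self):
        ref = np.full((4, 4, 2), 100.0)
        mask = np.ones((4, 4, 2), bool)
        assert mean_relative_deviation(ref, ref, mask) == 0.0

    def test_ten_percent(self):
        ref = np.full((4, 4, 2), 50.0)
        mask = np.ones((4, 4, 2), bool)
        assert mean_relative_deviation(1.1 * ref, ref, mask) == pytest.approx(0.1)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        test = rng.uniform(500, 1500, (5, 5, 2))
        ref = rng.uniform(500, 1500, (5, 5, 2))
        mask = rng.random((5, 5, 2)) > 0.4
        expected = np.mean(
            [
                abs(test[i] - ref[i]) / ref[i]
                for i in np.ndindex(test.shape)
                if mask[i]
            ]
        )
        assert mean_relative_deviation(test, ref, mask) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_relative_deviation(
                np.ones((2, 2, 1)), np.ones((2, 2, 1)), np.zeros((2, 2, 1), bool)
            )


class TestPerLesionStats:
    def test_perfect_prediction_volumes(self):
        gt = np.zeros((20, 20, 4), bool)
        gt[2:7, 2:7, 1:3] = True  # 50 voxels at 1x1x2 mm = 100 ul
        table = per_lesion_stats(gt, gt, voxel_size=(1.0, 1.0, 2.0))
        assert len(table) == 1
        assert table.loc[0, "volume_ul"] == pytest.approx(100.0)
        assert table.loc[0, "dice"] == 1.0
        assert table.loc[0, "predicted_volume_ul"] == pytest.approx(100.0)
        assert bool(table.loc[0, "detected"])

    def test_missed_lesion_row(self):
        gt = _two_lesion_volume()
        pred = gt.copy()
        pred[12:16, 12:16, 2:5] = False  # miss lesion B entirely
        table = per_lesion_stats(gt, pred)
        assert len(table) == 2
        missed = table[~table["detected"]]
        assert len(missed) == 1
        assert missed.iloc[0]["dice"] == 0.0
        assert missed.iloc[0]["predicted_volume_ul"] == 0.0

    def test_volumes_sum_to_total(self):
        rng = np.random.default_rng(5)
        gt = rng.random((16, 16, 6)) > 0.9
        table = per_lesion_stats(gt, np.zeros_like(gt), voxel_size=(1, 1, 2))
        assert table["volume_ul"].sum() == pytest.approx(gt.sum() * 2.0)

    def test_exact_prediction_on_identity_line(self):
        gt = _two_lesion_volume()
        table = per_lesion_stats(gt, gt)
        np.testing.assert_allclose(table["predicted_volume_ul"], table["volume_ul"])


class TestLesionProfile:
    def test_flat_map_zero_increase(self):
        comp = np.zeros((16, 16, 4), bool)
        comp[6:10, 6:10, 1:3] = True
        nawm = np.zeros_like(comp)
        nawm[:4, :4, :] = True
        t1 = np.full(comp.shape, 800.0)
        out = lesion_profile(t1, t1, np.zeros(comp.shape), comp, nawm)
        np.testing.assert_allclose(out["horizontal"]["dt1_percent"], 0.0, atol=1e-9)
        np.testing.assert_allclose(out["vertical"]["dt1_percent"], 0.0, atol=1e-9)

    def test_thirty_percent_elevation(self):
        comp = np.zeros((16, 16, 4), bool)
        comp[6:10, 6:10, 1:3] = True
        nawm = np.zeros_like(comp)
        nawm[:4, :4, :] = True
        t1 = np.full(comp.shape, 1000.0)
        t1[comp] = 1300.0
        out = lesion_profile(t1, t1, comp.astype(float), comp, nawm)
        assert out["dt1_percent"][comp] == pytest.approx(30.0)

    def test_probability_colocalizes_with_elevation(self):
        # gaussian-bump lesion: argmax of probability within 2 voxels of
        # argmax percent-increase along the cut
        shape = (24, 24, 4)
        comp = np.zeros(shape, bool)
        comp[10:14, 10:14, 1:3] = True
        bump = ndimage.gaussian_filter(comp.astype(float), 1.5)
        bump /= bump.max()
        nawm = np.zeros(shape, bool)
        nawm[:5, :5, :] = True
        t1 = 800.0 * (1.0 + 0.4 * bump)
        out = lesion_profile(t1, t1, bump, comp, nawm)
        h = out["horizontal"]
        assert abs(
            int(h["probability"].idxmax()) - int(h["dt1_percent"].idxmax())
        ) <= 2

    def test_multiple_components_rejected(self):
        comp = _two_lesion_volume()
        nawm = np.zeros_like(comp)
        nawm[0, 0, 0] = True
        with pytest.raises(ValueError, match="components"):
            lesion_profile(
                np.ones(comp.shape), np.ones(comp.shape), np.zeros(comp.shape),
                comp, nawm,
            )
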
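"""Lesion matching, detection metrics, effort metrics, simulated correction."""

import math

import numpy as np
import pytest
from helpers import brute_metrics

from annostream import (
    detection_metrics,
    effort_metrics,
    match_lesions,
    percent_excess,
    simulate_correction,
)
from conftest import label_volume


def _vols(computed, gt):
    return label_volume(computed), label_volume(gt)


class TestMatchLesions:
    def test_single_voxel_overlap_is_tp(self):
        gt = np.zeros((3, 6, 6))
        gt[1, 1:4, 1:4] = 1
        comp = np.zeros((3, 6, 6))
        comp[1, 3:6, 3:6] = 1  # shares exactly voxel (1,3,3)
        m = match_lesions(*_vols(comp, gt))
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 0, 0)

    def test_disjoint_computed_is_fp(self):
        gt = np.zeros((3, 6, 6))
        gt[0, 0, 0] = 1
        comp = np.zeros((3, 6, 6))
        comp[2, 4:6, 4:6] = 1
        m = match_lesions(*_vols(comp, gt))
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 1)

    def test_empty_computed_all_fn(self):
        gt = np.zeros((4, 12, 12))
        for i in range(4):
            gt[i, 3 * (i % 2) : 3 * (i % 2) + 2, 0:2] = 1
            gt[i, 8:10, 8:10] = 1
        m = match_lesions(*_vols(np.zeros_like(gt), gt))
        assert m.n_tp == 0 and m.n_fp == 0
        assert m.n_fn == m.n_gt > 0

    def test_largest_overlap_wins_assignment(self):
        gt = np.zeros((1, 10, 10))
        gt[0, 0:3, 0:3] = 1  # lesion A (9 px)
        gt[0, 0:3, 5:10] = 1  # lesion B (15 px)
        comp = np.zeros((1, 10, 10))
        comp[0, 0:3, 2:7] = 1  # overlaps A by 3 px, B by 6 px
        m = match_lesions(*_vols(comp, gt))
        # B gets the computed lesion; A is still detected (it overlaps), so
        # both count as TP and nothing is FP/FN
        assert m.n_tp == 2 and m.n_fp == 0 and m.n_fn == 0

    def test_conservation_invariants(self, rng):
        for _ in range(20):
            comp = (rng.random((6, 10, 10)) > 0.8).astype(np.uint8)
            gt = (rng.random((6, 10, 10)) > 0.8).astype(np.uint8)
            m = match_lesions(*_vols(comp, gt))
            assert m.n_tp + m.n_fn == m.n_gt
            matched_computed = {
                cl.component_id for pair in m.tp_pairs for cl in pair.computed_lesions
            }
            assert len(matched_computed) + m.n_fp == m.n_computed

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            match_lesions(
                label_volume(np.zeros((2, 2, 2))), label_volume(np.zeros((3, 2, 2)))
            )


class TestDetectionMetrics:
    def test_perfect_prediction_all_ones(self, small_phantom):
        _, gt, _ = small_phantom
        m = match_lesions(gt, gt)
        rep = detection_metrics(m)
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)
        assert (rep.dice, rep.dice_with_fn) == (1.0, 1.0)

    def test_half_covered_lesion_dice_two_thirds(self):
        gt = np.zeros((1, 4, 4))
        gt[0, 0:2, 0:4] = 1  # 8 voxels
        comp = np.zeros((1, 4, 4))
        comp[0, 0:2, 0:2] = 1  # 4 of them, no extras
        m = match_lesions(*_vols(comp, gt))
        assert detection_metrics(m).dice == pytest.approx(2 / 3)

    def test_counts_follow_definitions(self):
        gt = np.zeros((10, 40, 40))
        for i in range(10):  # 10 disjoint GT lesions (staggered columns)
            gt[i, 2:4, 2 + 3 * i : 4 + 3 * i] = 1
        comp = np.zeros((10, 40, 40))
        for i in range(8):  # 8 detected
            comp[i, 2:4, 2 + 3 * i : 4 + 3 * i] = 1
        for i in range(3):  # 3 disjoint spurious (separated slices)
            comp[2 * i, 30:32, 30:32] = 1
        m = match_lesions(*_vols(comp, gt))
        rep = detection_metrics(m)
        assert (m.n_tp, m.n_fp, m.n_fn) == (8, 3, 2)
        assert rep.precision == pytest.approx(8 / 11)
        assert rep.recall == pytest.approx(0.8)

    def test_empty_empty_convention(self):
        m = match_lesions(*_vols(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))))
        rep = detection_metrics(m)
        assert rep.precision == rep.recall == rep.dice == 1.0

    def test_no_computed_lesions_precision_missing(self):
        gt = np.zeros((2, 5, 5))
        gt[0, 1:3, 1:3] = 1
        m = match_lesions(*_vols(np.zeros_like(gt), gt))
        rep = detection_metrics(m)
        assert math.isnan(rep.precision)
        assert rep.recall == 0.0
        assert rep.dice_with_fn == 0.0

    def test_dice_with_fn_bounded_by_dice(self, rng):
        for _ in range(20):
            comp = (rng.random((5, 12, 12)) > 0.75).astype(np.uint8)
            gt = (rng.random((5, 12, 12)) > 0.75).astype(np.uint8)
            m = match_lesions(*_vols(comp, gt))
            rep = detection_metrics(m)
            if (m.n_fn + m.n_fp) > 0 and not math.isnan(rep.dice):
                assert rep.dice_with_fn <= rep.dice + 1e-12


class TestEffortMetrics:
    def test_ratios_follow_definitions(self):
        gt = np.zeros((10, 60, 60))
        for i in range(10):
            gt[i, 2:5, 2 + 5 * i : 5 + 5 * i] = 1
        comp = np.zeros((10, 60, 60))
        for i in range(8):
            comp[i, 2:5, 2 + 5 * i : 5 + 5 * i] = 1
        for i in range(3):
            comp[2 * i, 50:53, 50:53] = 1
        m = match_lesions(*_vols(comp, gt))
        rep = effort_metrics(m)
        assert rep.fnr == pytest.approx(0.2)
        assert rep.fpr == pytest.approx(0.3)
        assert rep.detection_clicks_fp == 3
        assert rep.detection_clicks_fn == 2

    def test_identical_masks_zero_effort(self, small_phantom):
        _, gt, _ = small_phantom
        m = match_lesions(gt, gt)
        rep = effort_metrics(m)
        assert rep.ccs == 0.0 and rep.contour_clicks == 0
        assert rep.fnr == 0.0 and rep.fpr == 0.0

    def test_ccs_from_contour_symmetric_difference(self):
        # GT: one 6x6 in-plane square -> 20 contour pixels; computed shifts
        # the right edge out by one column
        gt = np.zeros((1, 12, 12))
        gt[0, 2:8, 2:8] = 1
        comp = gt.copy()
        comp[0, 2:8, 8] = 1  # one extra column
        m = match_lesions(*_vols(comp, gt))
        rep = effort_metrics(m)
        oracle = brute_metrics(comp, gt)
        assert rep.ccs == pytest.approx(oracle["ccs"])
        assert rep.contour_clicks == oracle["contour_clicks"]

    def test_no_gt_lesions_ratios_missing(self):
        comp = np.zeros((2, 6, 6))
        comp[0, 1:3, 1:3] = 1
        m = match_lesions(*_vols(comp, np.zeros_like(comp)))
        rep = effort_metrics(m)
        assert math.isnan(rep.fnr) and math.isnan(rep.fpr)
        assert rep.detection_clicks_fp == 1

    def test_ccs_invariant_under_joint_translation(self):
        gt = np.zeros((3, 16, 16))
        gt[1, 2:7, 2:7] = 1
        comp = gt.copy()
        comp[1, 2:7, 7] = 1
        m1 = match_lesions(*_vols(comp, gt))
        gt2 = np.roll(np.roll(gt, 5, axis=1), 4, axis=2)
        comp2 = np.roll(np.roll(comp, 5, axis=1), 4, axis=2)
        m2 = match_lesions(*_vols(comp2, gt2))
        assert effort_metrics(m1).ccs == pytest.approx(effort_metrics(m2).ccs)

    def test_fn_delineation_clicks_counts_gt_contours(self):
        gt = np.zeros((1, 10, 10))
        gt[0, 2:7, 2:7] = 1  # 5x5 square: 16 contour pixels, all missed
        m = match_lesions(*_vols(np.zeros_like(gt), gt))
        rep = effort_metrics(m)
        assert rep.fn_delineation_clicks == 16
        assert rep.contour_clicks == 0


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_volumes(self):
        """Every reported metric equals direct voxel/pixel enumeration."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            shape = tuple(rng.integers(3, 17, size=3))
            comp = (rng.random(shape) > 0.75).astype(np.uint8)
            gt = (rng.random(shape) > 0.75).astype(np.uint8)
            m = match_lesions(*_vols(comp, gt))
            det = detection_metrics(m)
            eff = effort_metrics(m)
            oracle = brute_metrics(comp, gt)
            assert (m.n_tp, m.n_fp, m.n_fn) == (
                oracle["n_tp"], oracle["n_fp"], oracle["n_fn"],
            )
            for name, key in [
                ("precision", "precision"), ("recall", "recall"),
                ("dice", "dice"), ("dice_with_fn", "dice_with_fn"),
            ]:
                got, want = getattr(det, name), oracle[key]
                if want is None:
                    if not (comp.sum() == 0 and gt.sum() == 0):
                        assert math.isnan(got)
                else:
                    assert got == pytest.approx(want)
            for name in ("fnr", "fpr", "ccs"):
                got, want = getattr(eff, name), oracle[name]
                if want is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want)
            assert eff.contour_clicks == oracle["contour_clicks"]
            assert eff.fn_delineation_clicks == oracle["fn_delineation_clicks"]


class TestSimulateCorrection:
    def test_corrected_equals_gt_exactly(self, rng):
        comp = (rng.random((5, 10, 10)) > 0.8).astype(np.uint8)
        gt = (rng.random((5, 10, 10)) > 0.8).astype(np.uint8)
        corrected, report = simulate_correction(*_vols(comp, gt))
        np.testing.assert_array_equal(corrected.voxels, gt)

    def test_already_correct_costs_nothing(self, small_phantom):
        _, gt, _ = small_phantom
        corrected, report = simulate_correction(gt, gt)
        assert report.contour_clicks == 0
        assert report.detection_clicks_fp == report.detection_clicks_fn == 0
        assert report.fnr == 0.0 and report.fpr == 0.0

    def test_idempotent(self, rng):
        comp = (rng.random((4, 8, 8)) > 0.8).astype(np.uint8)
        gt = (rng.random((4, 8, 8)) > 0.8).astype(np.uint8)
        corrected, _ = simulate_correction(*_vols(comp, gt))
        again, report = simulate_correction(corrected, label_volume(gt))
        np.testing.assert_array_equal(again.voxels, gt)
        assert report.contour_clicks == 0 and report.n_fp == 0 and report.n_fn == 0


class TestPercentExcess:
    def test_definition(self):
        assert percent_excess(345, 150) == pytest.approx(130.0)
        assert percent_excess(75, 56) == pytest.approx(100 * 19 / 56)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_excess(10, 0)
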
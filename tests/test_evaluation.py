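from __future__ import annotations

import numpy as np
import pytest

from berrypheno.evaluation import (
    DEFAULT_IOU_THRESHOLDS,
    ErrorTally,
    average_precision,
    classify_errors,
    iou_matrix,
    match_instances,
    mean_average_precision,
    mean_iou,
)

from _oracles import ap_prefix_oracle
from conftest import disk_mask, instance, square_mask

FRAME = (100, 100)


def _random_fixture(rng, n_pred=5, n_gt=4, frame=(60, 60)):
    """Random squares with random scores; one image, one class."""
    gts, preds = [], []
    for _ in range(n_gt):
        r, c = rng.integers(0, 40, 2)
        gts.append(instance(square_mask(frame, r, c, 12, 12)))
    for _ in range(n_pred):
        r, c = rng.integers(0, 40, 2)
        preds.append(
            instance(square_mask(frame, r, c, 12, 12), score=float(rng.uniform(0.1, 1.0)))
        )
    return preds, gts, frame


class TestMatchInstances:
    def test_identical_prediction_is_tp(self):
        gt = [instance(disk_mask(FRAME, 50, 50, 10))]
        pred = [instance(disk_mask(FRAME, 50, 50, 10), score=0.9)]
        m = match_instances(pred, gt, 0.5, FRAME)
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 0, 0)
        assert m.pairs[0][2] == pytest.approx(1.0)

    def test_low_iou_is_fp_and_fn(self):
        gt = [instance(square_mask(FRAME, 0, 0, 10, 10))]
        pred = [instance(square_mask(FRAME, 0, 6, 10, 10), score=0.9)]  # IOU = 4/16
        m = match_instances(pred, gt, 0.5, FRAME)
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 1)

    def test_higher_score_claims_the_gt(self):
        gt = [instance(square_mask(FRAME, 0, 0, 10, 10))]
        p_hi = instance(square_mask(FRAME, 0, 1, 10, 10), score=0.9)  # IOU ~ 0.82
        p_lo = instance(square_mask(FRAME, 0, 2, 10, 10), score=0.8)  # IOU ~ 0.67
        m = match_instances([p_lo, p_hi], gt, 0.5, FRAME)
        assert m.n_tp == 1 and m.pairs[0][0] == 1  # index of p_hi in input order
        assert m.unmatched_preds == [0]

    def test_class_aware_blocks_cross_class_match(self):
        gt = [instance(disk_mask(FRAME, 50, 50, 10), "immature")]
        pred = [instance(disk_mask(FRAME, 50, 50, 10), "mature", score=0.9)]
        assert match_instances(pred, gt, 0.5, FRAME, class_aware=True).n_tp == 0
        assert match_instances(pred, gt, 0.5, FRAME, class_aware=False).n_tp == 1

    def test_rejects_bad_threshold_and_missing_scores(self):
        gt = [instance(disk_mask(FRAME, 50, 50, 10))]
        pred = [instance(disk_mask(FRAME, 50, 50, 10), score=0.9)]
        with pytest.raises(ValueError):
            match_instances(pred, gt, 0.0, FRAME)
        with pytest.raises(ValueError):
            match_instances([instance(disk_mask(FRAME, 50, 50, 10))], gt, 0.5, FRAME)

    def test_tp_fn_tp_fp_bookkeeping_random(self, rng):
        for _ in range(10):
            preds, gts, frame = _random_fixture(rng)
            for t in (0.3, 0.5, 0.8):
                m = match_instances(preds, gts, t, frame, class_aware=True)
                assert m.n_tp + m.n_fn == len(gts)
                assert m.n_tp + m.n_fp == len(preds)
                assert all(iou >= t for _, _, iou in m.pairs)


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        gt = [instance(disk_mask(FRAME, 50, 50, 10))]
        pred = [instance(disk_mask(FRAME, 50, 50, 10), score=1.0)]
        res = average_precision(pred, gt, "mature", 0.5, {"img": FRAME})
        assert res.ap == pytest.approx(1.0)

    def test_hand_enumerated_tp_fp_tp_sequence(self):
        """Two GT; detections in score order TP, FP, TP -> AP = 5/6."""
        gt = [
            instance(square_mask(FRAME, 0, 0, 10, 10)),
            instance(square_mask(FRAME, 40, 40, 10, 10)),
        ]
        preds = [
            instance(square_mask(FRAME, 0, 0, 10, 10), score=0.9),  # TP
            instance(square_mask(FRAME, 70, 70, 10, 10), score=0.8),  # FP
            instance(square_mask(FRAME, 40, 40, 10, 10), score=0.7),  # TP
        ]
        res = average_precision(preds, gt, "mature", 0.5, {"img": FRAME})
        assert res.recall.tolist() == pytest.approx([0.5, 0.5, 1.0])
        assert res.precision.tolist() == pytest.approx([1.0, 0.5, 2 / 3])
        assert res.ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_all_false_positives(self):
        gt = [instance(square_mask(FRAME, 0, 0, 10, 10))]
        preds = [instance(square_mask(FRAME, 60, 60, 10, 10), score=0.9)]
        assert average_precision(preds, gt, "mature", 0.5, {"img": FRAME}).ap == 0.0

    def test_rejects_missing_class(self):
        gt = [instance(square_mask(FRAME, 0, 0, 10, 10), "mature")]
        with pytest.raises(ValueError):
            average_precision([], gt, "immature", 0.5, {"img": FRAME})

    def test_matches_prefix_enumeration_oracle(self, rng):
        for _ in range(15):
            preds, gts, frame = _random_fixture(
                rng, n_pred=int(rng.integers(1, 7)), n_gt=int(rng.integers(1, 5))
            )
            iou = iou_matrix(preds, gts, frame).tolist()
            scores = [p.score for p in preds]
            for t in (0.3, 0.5, 0.75):
                got = average_precision(preds, gts, "mature", t, {"img": frame}).ap
                want = ap_prefix_oracle(scores, iou, len(gts), t)
                assert got == pytest.approx(want, abs=1e-12)

    def test_shuffling_input_order_changes_nothing(self, rng):
        preds, gts, frame = _random_fixture(rng, n_pred=6, n_gt=4)
        base = average_precision(preds, gts, "mature", 0.5, {"img": frame}).ap
        for _ in range(5):
            perm = [preds[i] for i in rng.permutation(len(preds))]
            assert average_precision(perm, gts, "mature", 0.5, {"img": frame}).ap == base


class TestMeanAveragePrecision:
    def test_perfect_predictions_everywhere(self):
        gts = [
            instance(disk_mask(FRAME, 30, 30, 10), "mature"),
            instance(disk_mask(FRAME, 70, 70, 10), "immature"),
        ]
        preds = [
            instance(disk_mask(FRAME, 30, 30, 10), "mature", score=1.0),
            instance(disk_mask(FRAME, 70, 70, 10), "immature", score=1.0),
        ]
        res = mean_average_precision(preds, gts, {"img": FRAME})
        assert all(v == pytest.approx(1.0) for v in res["map"].values())

    def test_shrunken_masks_flip_at_known_iou(self):
        """Predictions nested in GT at IOU exactly 0.7 flip mAP from 1 to 0."""
        gts, preds = [], []
        for i, label in enumerate(["mature", "immature"]):
            r = 10 + 40 * i
            gts.append(instance(square_mask(FRAME, r, 10, 20, 20), label))
            preds.append(
                instance(square_mask(FRAME, r, 10, 20, 14), label, score=0.9)
            )  # IOU = 280/400 = 0.7
        res = mean_average_precision(preds, gts, {"img": FRAME})
        for t, v in res["map"].items():
            if t <= 0.65:
                assert v == pytest.approx(1.0)
            elif t >= 0.75:
                assert v == pytest.approx(0.0)

    def test_monotone_non_increasing_in_threshold(self, rng):
        for _ in range(5):
            preds, gts, frame = _random_fixture(rng, n_pred=6, n_gt=5)
            res = mean_average_precision(preds, gts, {"img": frame})
            values = [res["map"][t] for t in sorted(res["map"])]
            assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_absent_class_excluded_with_warning(self):
        gts = [instance(disk_mask(FRAME, 30, 30, 10), "mature")]
        preds = [instance(disk_mask(FRAME, 30, 30, 10), "mature", score=1.0)]
        with pytest.warns(UserWarning, match="absent"):
            res = mean_average_precision(preds, gts, {"img": FRAME})
        assert "immature" not in res["per_class"]


class TestMeanIou:
    def test_arithmetic_mean_of_tp_pairs(self):
        gt = [
            instance(square_mask(FRAME, 0, 0, 10, 10)),
            instance(square_mask(FRAME, 40, 40, 10, 10)),
        ]
        preds = [
            instance(square_mask(FRAME, 0, 0, 10, 10), score=0.9),  # IOU 1.0
            instance(square_mask(FRAME, 40, 40, 10, 8), score=0.8),  # IOU 0.8
        ]
        m = match_instances(preds, gt, 0.5, FRAME)
        assert mean_iou(m) == pytest.approx(0.9)

    def test_matches_direct_recomputation(self, rng):
        matches = []
        expected = []
        for _ in range(20):
            preds, gts, frame = _random_fixture(rng)
            m = match_instances(preds, gts, 0.3, frame)
            matches.append(m)
            expected.extend(iou for _, _, iou in m.pairs)
        assert mean_iou(matches) == pytest.approx(float(np.mean(expected)))

    def test_rejects_zero_tp(self):
        with pytest.raises(ValueError):
            mean_iou(
                match_instances(
                    [instance(square_mask(FRAME, 0, 0, 5, 5), score=0.5)],
                    [instance(square_mask(FRAME, 50, 50, 5, 5))],
                    0.5,
                    FRAME,
                )
            )


class TestClassifyErrors:
    def test_perfect_predictions_no_errors(self):
        gts = [instance(disk_mask(FRAME, 30, 30, 10)), instance(disk_mask(FRAME, 70, 70, 10))]
        preds = [instance(g.mask, score=0.9) for g in gts]
        assert classify_errors(preds, gts, FRAME).total == 0

    def test_missed_detection(self):
        gts = [instance(disk_mask(FRAME, 30, 30, 10))]
        tally = classify_errors([], gts, FRAME)
        assert tally.missed == 1 and tally.total == 1

    def test_two_as_one(self):
        # one 30x10 prediction covering two 10x10 squares at IOU 1/3 each
        gts = [
            instance(square_mask(FRAME, 0, 0, 10, 10)),
            instance(square_mask(FRAME, 0, 20, 10, 10)),
        ]
        preds = [instance(square_mask(FRAME, 0, 0, 10, 30), score=0.9)]
        tally = classify_errors(preds, gts, FRAME)
        assert tally.two_as_one == 1 and tally.total == 1

    def test_one_as_two(self):
        # two 10x4 fragments of a 10x10 berry: each IOU 0.4, union IOU 0.8
        gts = [instance(square_mask(FRAME, 0, 0, 10, 10))]
        preds = [
            instance(square_mask(FRAME, 0, 0, 10, 4), score=0.8),
            instance(square_mask(FRAME, 0, 6, 10, 4), score=0.7),
        ]
        tally = classify_errors(preds, gts, FRAME)
        assert tally.one_as_two == 1 and tally.total == 1

    def test_partial_detection(self):
        # prediction overlaps 30% of the berry only
        gts = [instance(square_mask(FRAME, 0, 0, 10, 10))]
        preds = [instance(square_mask(FRAME, 0, 7, 10, 10), score=0.8)]  # IOU 30/170
        tally = classify_errors(preds, gts, FRAME)
        assert tally.partial == 1 and tally.total == 1

    def test_rejects_floor_above_primary(self):
        with pytest.raises(ValueError):
            classify_errors([], [], FRAME, primary_threshold=0.5, floor_threshold=0.5)

    def test_tally_addition(self):
        a = ErrorTally(one_as_two=1, missed=2)
        b = ErrorTally(two_as_one=3, partial=1)
        c = a + b
        assert (c.one_as_two, c.missed, c.two_as_one, c.partial) == (1, 2, 3, 1)
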
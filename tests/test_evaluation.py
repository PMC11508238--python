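"""Detection and counting metrics."""

import numpy as np
import pandas as pd
import pytest

from icucount.evaluation import (
    MAP_IOU_GRID,
    RECALL_GRID,
    average_precision,
    counting_accuracy,
    iou,
    mean_average_precision,
    regression_errors,
    round_half_up,
)
from icucount.io import ValidationError
from icucount.types import BoundingBox, Category, GroundTruthObject, corners_to_box

from conftest import make_detection, make_frame


def counts_df(patient, clinician, visitor):
    n = len(patient)
    return pd.DataFrame(
        {"patient": patient, "clinician": clinician, "visitor": visitor},
        index=pd.Index(range(n), name="frame_index"),
    ).astype(float)


def oracle_ap(detections, truth, iou_threshold, recall_grid=RECALL_GRID):
    """Brute-force AP: enumerate the precision-recall staircase point by
    point and take, for every grid level r, the best precision among all
    prefixes of the ranked list whose recall reaches r."""
    order = sorted(range(len(detections)), key=lambda k: -detections[k][2])
    matched = set()
    points = []  # (recall, precision) after each prefix
    tp = 0
    for rank, k in enumerate(order, start=1):
        fi, box, _ = detections[k]
        best, best_t = 0.0, None
        for t_idx, (tfi, tbox) in enumerate(truth):
            if tfi != fi or t_idx in matched:
                continue
            ov = iou(box, tbox)
            if ov >= iou_threshold and ov > best:
                best, best_t = ov, t_idx
        if best_t is not None:
            matched.add(best_t)
            tp += 1
        points.append((tp / len(truth), tp / rank))
    total = 0.0
    for r in recall_grid:
        candidates = [p for rec, p in points if rec >= r]
        total += max(candidates) if candidates else 0.0
    return total / len(recall_grid)


class TestIoU:
    def test_identical(self):
        b = BoundingBox(5, 5, 4, 4)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(10, 10, 2, 2)) == 0.0

    def test_hand_geometry(self):
        a = corners_to_box(0, 0, 2, 2)
        b = corners_to_box(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        truth = [(0, BoundingBox(5, 5, 4, 4))]
        dets = [(0, BoundingBox(5, 5, 4, 4), 0.9)]
        assert average_precision(dets, truth) == pytest.approx(1.0)

    def test_no_detections(self):
        assert average_precision([], [(0, BoundingBox(5, 5, 4, 4))]) == 0.0

    def test_empty_truth_defined_zero(self):
        assert average_precision([(0, BoundingBox(5, 5, 4, 4), 0.9)], []) == 0.0

    def test_half_recall_hand_value(self):
        # two truths, one perfectly matched detection: precision 1 up to
        # recall 0.5, zero beyond -> 51 of 101 grid points
        truth = [(0, BoundingBox(5, 5, 4, 4)), (1, BoundingBox(5, 5, 4, 4))]
        dets = [(0, BoundingBox(5, 5, 4, 4), 0.9)]
        assert average_precision(dets, truth) == pytest.approx(51 / 101)

    def test_matches_staircase_oracle(self, rng):
        for _ in range(100):
            n_truth = int(rng.integers(1, 10))
            n_det = int(rng.integers(0, 20))
            truth = [
                (int(rng.integers(0, 3)),
                 BoundingBox(rng.uniform(0, 50), rng.uniform(0, 50),
                             rng.uniform(2, 12), rng.uniform(2, 12)))
                for _ in range(n_truth)
            ]
            dets = [
                (int(rng.integers(0, 3)),
                 BoundingBox(rng.uniform(0, 50), rng.uniform(0, 50),
                             rng.uniform(2, 12), rng.uniform(2, 12)),
                 float(rng.uniform(0, 1)))
                for _ in range(n_det)
            ]
            thr = float(rng.choice([0.3, 0.5, 0.7]))
            assert average_precision(dets, truth, thr) == pytest.approx(
                oracle_ap(dets, truth, thr), abs=1e-9
            )

    def test_monotone_in_iou_threshold(self, rng):
        truth = [
            (i, BoundingBox(rng.uniform(0, 50), rng.uniform(0, 50), 10, 10))
            for i in range(8)
        ]
        dets = [
            (fi, BoundingBox(b.cx + rng.uniform(0, 4), b.cy, 10, 10), float(rng.uniform(0.2, 1)))
            for fi, b in truth
        ]
        aps = [average_precision(dets, truth, t) for t in MAP_IOU_GRID]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))
        assert all(0.0 <= a <= 1.0 for a in aps)


class TestMeanAveragePrecision:
    def _frames_and_truth(self, det_shift):
        truth = [
            GroundTruthObject(1, Category.CLINICIAN, BoundingBox(5, 0.5, 10, 1), i)
            for i in range(4)
        ]
        frames = [
            make_frame(i, [make_detection(cx=5 + det_shift, cy=0.5, w=10, h=1,
                                          category=Category.CLINICIAN)])
            for i in range(4)
        ]
        return frames, truth

    def test_perfect_detections(self):
        frames, truth = self._frames_and_truth(0.0)
        out = mean_average_precision(frames, truth)
        assert out["map"] == pytest.approx(1.0)

    def test_iou_point_six_passes_three_thresholds(self):
        # shift 2.5 of a 10-wide box: intersection 7.5, union 12.5, IoU 0.6
        frames, truth = self._frames_and_truth(2.5)
        out = mean_average_precision(frames, truth)
        aps = out["per_category"]["clinician"]["ap_by_iou"]
        assert sum(v for v in aps.values()) == pytest.approx(3.0)
        assert out["map"] == pytest.approx(3 / 10)

    def test_headline_is_mean_of_thresholds(self):
        frames, truth = self._frames_and_truth(1.0)
        out = mean_average_precision(frames, truth)
        cat = out["per_category"]["clinician"]
        assert cat["map"] == pytest.approx(np.mean(list(cat["ap_by_iou"].values())))

    def test_absent_category_excluded(self):
        frames, truth = self._frames_and_truth(0.0)
        out = mean_average_precision(frames, truth)
        assert list(out["per_category"]) == ["clinician"]


class TestCountingAccuracy:
    def test_identical_is_hundred(self):
        t = counts_df([1, 1], [2, 0], [0, 1])
        acc = counting_accuracy(t, t)
        assert all(v == 100.0 for v in acc.values())

    def test_two_of_three(self):
        pred = counts_df([1, 1, 1], [1, 2, 1], [0, 0, 0])
        truth = counts_df([1, 1, 1], [1, 2, 0], [0, 0, 0])
        acc = counting_accuracy(pred, truth)
        assert acc["clinician"] == pytest.approx(100 * 2 / 3)
        assert acc["patient"] == 100.0

    def test_half_rounds_up(self):
        assert round_half_up(0.5) == 1.0
        assert round_half_up(1.5) == 2.0
        assert round_half_up(0.49) == 0.0
        pred = counts_df([0.5], [0], [0])
        truth = counts_df([1], [0], [0])
        assert counting_accuracy(pred, truth)["patient"] == 100.0

    def test_misaligned_tables_rejected(self):
        pred = counts_df([1], [0], [0])
        truth = counts_df([1, 1], [0, 0], [0, 0])
        with pytest.raises(ValidationError):
            counting_accuracy(pred, truth)


class TestRegressionErrors:
    def test_zero_error(self):
        t = counts_df([1, 1], [2, 0], [0, 1])
        errs = regression_errors(t, t)
        for cat in errs.values():
            assert cat["mae"] == 0.0 and cat["mse"] == 0.0 and cat["rmse"] == 0.0

    def test_hand_arithmetic_with_zero_truth_policy(self):
        pred = counts_df([0, 0, 0], [1, 0, 1], [0, 0, 0])
        truth = counts_df([0, 0, 0], [2, 0, 1], [0, 0, 0])
        errs = regression_errors(pred, truth)["clinician"]
        assert errs["mae"] == pytest.approx(1 / 3)
        assert errs["mse"] == pytest.approx(1 / 3)
        assert errs["rmse"] == pytest.approx(np.sqrt(1 / 3))
        # zero-truth frame skipped: (|2-1|/2 + 0)/2
        assert errs["mre"] == pytest.approx(0.25)

    def test_error_scaling(self):
        truth = counts_df([0] * 4, [2, 2, 2, 2], [0] * 4)
        pred1 = counts_df([0] * 4, [1, 1, 1, 1], [0] * 4)
        pred2 = counts_df([0] * 4, [0, 0, 0, 0], [0] * 4)
        e1 = regression_errors(pred1, truth)["clinician"]
        e2 = regression_errors(pred2, truth)["clinician"]
        assert e2["mae"] == pytest.approx(2 * e1["mae"])
        assert e2["mse"] == pytest.approx(4 * e1["mse"])

    def test_metric_identities(self, rng):
        pred = counts_df(*(rng.uniform(0, 3, size=20) for _ in range(3)))
        truth = counts_df(*(rng.integers(0, 4, size=20) for _ in range(3)))
        errs = regression_errors(pred, truth)
        for cat in errs.values():
            assert cat["rmse"] ** 2 == pytest.approx(cat["mse"])
            assert cat["mae"] <= cat["rmse"] + 1e-12

    def test_accuracy_hundred_iff_mae_zero_on_integer_counts(self, rng):
        pred = counts_df(*(rng.integers(0, 3, size=15) for _ in range(3)))
        truth = counts_df(*(rng.integers(0, 3, size=15) for _ in range(3)))
        acc = counting_accuracy(pred, truth)
        errs = regression_errors(pred, truth)
        for cat in acc:
            assert (acc[cat] == 100.0) == (errs[cat]["mae"] == 0.0)
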
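import numpy as np
import pytest

from cytocluster.errors import RegistrationError, UndefinedMetricError
from cytocluster.imageio_core import BinaryMask
from cytocluster.metrics_eval import (
    MAP_THRESHOLDS,
    ConfusionCounts,
    DetectionSet,
    accuracy,
    aggregate_cv,
    average_precision,
    iou,
    map_range,
    precision_recall_f1,
)


class TestConfusionMetrics:
    def test_accuracy_five_sixths(self):
        assert accuracy(ConfusionCounts(tp=3, tn=2, fp=1, fn=0)) == pytest.approx(5 / 6)

    def test_accuracy_all_correct(self):
        assert accuracy(ConfusionCounts(tp=4, tn=6)) == 1.0

    def test_accuracy_half(self):
        assert accuracy(ConfusionCounts(1, 1, 1, 1)) == 0.5

    def test_accuracy_undefined(self):
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)

    def test_prf_forced_arithmetic(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=3, fp=1, fn=0))
        assert p == 0.75 and r == 1.0 and f1 == pytest.approx(6 / 7)

    def test_prf_zero_denominator_policy(self, caplog):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=0, fp=0, fn=2))
        assert p == 0.0 and r == 0.0 and f1 == 0.0

    def test_prf_all_ten(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp=10, fp=10, fn=10))
        assert (p, r, f1) == (0.5, 0.5, 0.5)

    def test_f1_harmonic_identity(self):
        c = ConfusionCounts(tp=7, fp=3, fn=2)
        p, r, f1 = precision_recall_f1(c)
        assert f1 == pytest.approx(2 * p * r / (p + r))
        assert f1 <= min(2 * p, 2 * r)


class TestIoU:
    def test_identical(self):
        m = BinaryMask(np.eye(5, dtype=bool))
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = BinaryMask(np.eye(5, dtype=bool))
        b = BinaryMask(~np.eye(5, dtype=bool))
        assert iou(a, b) == 0.0

    def test_forced_third(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[:10, :10] = True  # 100 px
        b[5:15, :10] = True  # 100 px, 50 shared
        assert iou(BinaryMask(a), BinaryMask(b)) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        e = BinaryMask(np.zeros((4, 4), dtype=bool))
        assert iou(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(RegistrationError):
            iou(BinaryMask(np.eye(4, dtype=bool)), BinaryMask(np.eye(5, dtype=bool)))

    def test_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert iou((0, 0, 10, 10), (0, 5, 10, 15)) == pytest.approx(1 / 3)


def _box_detection_set(ious, confs, truth_boxes):
    """Build a DetectionSet of boxes where prediction i has the requested
    IoU with its best truth (constructed along disjoint rows)."""
    preds = []
    for i, (v, c) in enumerate(zip(ious, confs)):
        r0 = truth_boxes[i % len(truth_boxes)][0]
        # prediction nested in a unit-height truth strip of length 100:
        # intersection = w, union = 100, so IoU = w / 100
        preds.append(((r0, 0.0, r0 + 1.0, 100.0 * v), c))
    return DetectionSet(predictions=tuple(preds), truths=tuple(truth_boxes))


def _brute_force_ap(d: DetectionSet, thr: float) -> float:
    """Independent oracle: greedy matching re-implemented with explicit
    loops, then the exact (all-point, unsampled) area under the
    interpolated precision-recall envelope."""
    order = sorted(
        range(len(d.predictions)), key=lambda i: (-d.predictions[i][1], i)
    )
    used = set()
    flags = []
    for i in order:
        best, best_v = None, 0.0
        for j in range(len(d.truths)):
            if j in used:
                continue
            v = iou(d.predictions[i][0], d.truths[j])
            if v > best_v:
                best, best_v = j, v
        if best is not None and best_v >= thr:
            used.add(best)
            flags.append(1)
        else:
            flags.append(0)
    precisions, recalls = [], []
    tp = 0
    for rank, f in enumerate(flags, start=1):
        tp += f
        precisions.append(tp / rank)
        recalls.append(tp / len(d.truths))
    # exact integral of p_int(r) = max precision at recall >= r
    ap = 0.0
    prev_r = 0.0
    for r in sorted(set(recalls)):
        if r <= prev_r:
            continue
        p_int = max(p for p, rr in zip(precisions, recalls) if rr >= r)
        ap += (r - prev_r) * p_int
        prev_r = r
    return ap


def _random_mask_detection_set(rng, n_pred, n_truth):
    truths = []
    for _ in range(n_truth):
        g = np.zeros((24, 24), dtype=bool)
        r, c = rng.integers(0, 12, 2)
        g[r : r + rng.integers(4, 12), c : c + rng.integers(4, 12)] = True
        truths.append(BinaryMask(g))
    preds = []
    for _ in range(n_pred):
        g = np.zeros((24, 24), dtype=bool)
        r, c = rng.integers(0, 12, 2)
        g[r : r + rng.integers(4, 12), c : c + rng.integers(4, 12)] = True
        preds.append((BinaryMask(g), float(rng.random())))
    return DetectionSet(predictions=tuple(preds), truths=tuple(truths))


class TestAveragePrecision:
    def test_perfect_detection(self):
        m = BinaryMask(np.eye(8, dtype=bool))
        d = DetectionSet(predictions=((m, 0.9),), truths=(m,))
        for thr in MAP_THRESHOLDS:
            assert average_precision(d, thr) == 1.0

    def test_no_predictions(self):
        d = DetectionSet(predictions=(), truths=(BinaryMask(np.eye(4, dtype=bool)),))
        assert average_precision(d, 0.5) == 0.0

    def test_no_truths_undefined(self):
        m = BinaryMask(np.eye(4, dtype=bool))
        with pytest.raises(UndefinedMetricError):
            average_precision(DetectionSet(predictions=((m, 0.5),), truths=()), 0.5)

    def test_small_case_against_oracle(self):
        truths = [(0.0, 0.0, 1.0, 100.0), (10.0, 0.0, 11.0, 100.0)]
        d = _box_detection_set([0.9, 0.3, 0.8], [0.9, 0.8, 0.7], truths)
        got = average_precision(d, 0.5)
        want = _brute_force_ap(d, 0.5)
        assert got == pytest.approx(want, abs=0.01)

    def test_randomized_against_oracle(self):
        """100 seeded small instances within 0.01 of the all-point oracle."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            d = _random_mask_detection_set(
                rng, n_pred=int(rng.integers(1, 11)), n_truth=int(rng.integers(1, 6))
            )
            thr = float(rng.uniform(0.3, 0.9))
            assert average_precision(d, thr) == pytest.approx(
                _brute_force_ap(d, thr), abs=0.01
            )

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        d = _random_mask_detection_set(rng, 6, 3)
        aps = [average_precision(d, t) for t in MAP_THRESHOLDS]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


class TestMapRange:
    def test_perfect(self):
        m = BinaryMask(np.eye(8, dtype=bool))
        d = DetectionSet(predictions=((m, 1.0),), truths=(m,))
        assert map_range(d) == 1.0

    def test_empty_predictions(self):
        d = DetectionSet(predictions=(), truths=(BinaryMask(np.eye(4, dtype=bool)),))
        assert map_range(d) == 0.0

    def test_threshold_count(self):
        assert len(MAP_THRESHOLDS) == 10
        assert MAP_THRESHOLDS[0] == 0.50 and MAP_THRESHOLDS[-1] == 0.95

    def test_mixed_case_matches_per_threshold_oracle(self):
        truths = [(0.0, 0.0, 1.0, 100.0), (10.0, 0.0, 11.0, 100.0)]
        d = _box_detection_set([0.9, 0.3, 0.8], [0.9, 0.8, 0.7], truths)
        want = np.mean([_brute_force_ap(d, t) for t in MAP_THRESHOLDS])
        assert map_range(d) == pytest.approx(want, abs=0.01)


class TestAggregateCV:
    def test_identical_folds_zero_sd(self):
        folds = [{"acc": 0.9}] * 5
        assert aggregate_cv(folds)["acc"] == (pytest.approx(0.9), 0.0)

    def test_two_folds(self):
        out = aggregate_cv([{"acc": 0.9}, {"acc": 1.0}])
        mean, sd = out["acc"]
        assert mean == pytest.approx(0.95)
        assert sd == pytest.approx(0.0707, abs=1e-4)

    def test_single_fold_flagged(self, caplog):
        out = aggregate_cv([{"acc": 0.8}])
        assert out["acc"] == (pytest.approx(0.8), 0.0)

    def test_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            aggregate_cv([])
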
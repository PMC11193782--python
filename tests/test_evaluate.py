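"""Detection metrics against brute-force oracles."""

import numpy as np
import pytest

from melondet.evaluate import (FPSReport, average_precision, confusion_matrix,
                               evaluate_detections, match_detections,
                               precision_recall)
from melondet.head import Detection
from melondet.losses import iou_matrix
from tests.conftest import random_boxes


def det(box, cid, score):
    return Detection(np.asarray(box, float), cid, score)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_match_perfect_detections():
    gts = np.array([[0, 0, 10, 10], [20, 20, 30, 30]])
    dets = [det(g, 0, 0.9) for g in gts]
    tp, _ = match_detections(dets, gts, np.zeros(2), 0.5)
    assert tp.all()


def test_match_no_detections_gives_all_fn():
    tp, _ = match_detections([], np.array([[0, 0, 1, 1]] * 3), np.zeros(3))
    assert len(tp) == 0  # three unmatched ground truths remain as FN


def test_match_double_detection_is_one_tp_one_fp():
    gts = np.array([[0, 0, 10, 10]])
    dets = [det([0, 0, 10, 10], 0, 0.9), det([1, 1, 10, 10], 0, 0.8)]
    tp, matched = match_detections(dets, gts, np.zeros(1), 0.5)
    assert tp.tolist() == [True, False]
    assert matched.tolist() == [0, -1]


def test_precision_recall_cases():
    assert precision_recall(10, 0, 0) == (1.0, 1.0)
    assert precision_recall(8, 2, 2) == (0.8, 0.8)
    assert precision_recall(0, 0, 5) == (0.0, 0.0)
    with pytest.raises(ValueError):
        precision_recall(-1, 0, 0)


# ---------------------------------------------------------------------------
# average precision vs an exhaustive envelope oracle
# ---------------------------------------------------------------------------

def brute_force_ap(scores, is_tp, n_gt):
    """Independent 101-point AP: for each recall point scan every prefix
    of the confidence-ranked list for the best achievable precision."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    flags = np.asarray(is_tp, bool)[order]
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        tp = fp = 0
        for f in flags:
            tp += int(f)
            fp += int(not f)
            if tp / n_gt >= r - 1e-12:
                best = max(best, tp / (tp + fp))
        total += best
    return total / 101


def test_ap_all_correct_is_one(rng):
    scores = rng.uniform(0.1, 1, 10)
    assert average_precision(scores, np.ones(10, bool), 10) == pytest.approx(1.0)


def test_ap_worked_example_against_oracle():
    scores = np.array([0.9, 0.8, 0.7])
    flags = np.array([True, False, True])
    got = average_precision(scores, flags, 2)
    assert got == pytest.approx(brute_force_ap(scores, flags, 2), abs=1e-9)


def test_ap_matches_brute_force_on_random_instances(rng):
    for _ in range(25):
        n = int(rng.integers(1, 50))
        n_gt = int(rng.integers(1, 20))
        scores = rng.uniform(0, 1, n)
        flags = rng.uniform(0, 1, n) < 0.5
        flags[: min(n, n_gt)] &= True  # arbitrary pattern is fine
        got = average_precision(scores, flags, n_gt)
        ref = brute_force_ap(scores, flags, n_gt)
        assert got == pytest.approx(ref, abs=1e-9)


def test_ap_invariant_under_monotone_confidence_transform(rng):
    scores = rng.uniform(0, 1, 30)
    flags = rng.uniform(0, 1, 30) < 0.6
    base = average_precision(scores, flags, 12)
    assert average_precision(scores ** 3, flags, 12) == pytest.approx(base)
    assert average_precision(0.1 + 0.5 * scores, flags, 12) \
        == pytest.approx(base)


def test_ap_of_empty_and_undefined_cases():
    assert average_precision(np.array([]), np.array([]), 5) == 0.0
    assert np.isnan(average_precision(np.array([0.5]), np.array([True]), 0))


# ---------------------------------------------------------------------------
# report-level metrics
# ---------------------------------------------------------------------------

def _per_image_case(rng, n_images=6, max_gt=4, noise=4.0, drop=0.3):
    per_image = []
    for _ in range(n_images):
        n = int(rng.integers(1, max_gt + 1))
        gts = random_boxes(rng, n, 0, 80, min_size=8)
        classes = rng.integers(0, 3, n)
        dets = []
        for b, c in zip(gts, classes):
            if rng.uniform() > drop:
                shifted = b + rng.normal(0, noise, 4)
                shifted[2:] = np.maximum(shifted[2:], shifted[:2] + 1)
                dets.append(det(shifted, int(c), float(rng.uniform(0.3, 1))))
        for _ in range(int(rng.integers(0, 3))):  # spurious detections
            dets.append(det(random_boxes(rng, 1, 0, 80, 8)[0],
                            int(rng.integers(0, 3)),
                            float(rng.uniform(0.05, 0.9))))
        per_image.append((dets, gts, classes))
    return per_image


def test_map50_bounds_map5095(rng):
    for _ in range(5):
        report = evaluate_detections(_per_image_case(rng))
        assert report.map50 >= report.map50_95 - 1e-9


def test_mean_ap_is_arithmetic_mean():
    # three classes with AP 1.0, 0.5, 0.0 average to 0.5
    gts = {0: np.array([[0, 0, 10, 10]]), 1: np.array([[0, 0, 10, 10],
                                                       [20, 20, 30, 30]]),
           2: np.array([[40, 40, 50, 50]])}
    per_image = [(
        [det([0, 0, 10, 10], 0, 0.9),          # class 0: perfect -> AP 1
         det([0, 0, 10, 10], 1, 0.9),          # class 1: one of two -> AP 0.5
         det([70, 70, 80, 80], 2, 0.9)],       # class 2: miss -> AP 0
        np.concatenate([gts[0], gts[1], gts[2]]),
        np.array([0, 1, 1, 2]),
    )]
    report = evaluate_detections(per_image)
    assert report.per_class["immature"].ap50 == pytest.approx(1.0)
    assert report.per_class["semi-mature"].ap50 == pytest.approx(0.5, abs=0.01)
    assert report.per_class["mature"].ap50 == pytest.approx(0.0)
    assert report.map50 == pytest.approx(
        np.mean([report.per_class[k].ap50 for k in report.per_class]), abs=1e-9)


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def brute_force_confusion(per_image, conf, thr):
    m = np.zeros((4, 4), np.int64)
    for dets, gts, classes in per_image:
        dets = sorted([d for d in dets if d.score >= conf],
                      key=lambda d: -d.score)
        used = set()
        for d in dets:
            best, best_iou = -1, thr
            for j in range(len(gts)):
                if j in used:
                    continue
                v = iou_matrix(d.box, gts[j])[0, 0]
                if v > best_iou:
                    best, best_iou = j, v
            if best >= 0:
                used.add(best)
                m[d.class_id, classes[best]] += 1
            else:
                m[d.class_id, 3] += 1
        for j in range(len(gts)):
            if j not in used:
                m[3, classes[j]] += 1
    return m


def test_confusion_perfect_predictions_are_diagonal():
    gts = np.array([[0, 0, 10, 10], [20, 20, 30, 30]])
    classes = np.array([0, 2])
    per_image = [([det(gts[0], 0, 0.9), det(gts[1], 2, 0.8)], gts, classes)]
    m = confusion_matrix(per_image)
    assert m[0, 0] == 1 and m[2, 2] == 1 and m.sum() == 2


def test_confusion_no_detections_populates_background_row():
    gts = np.array([[0, 0, 10, 10]])
    m = confusion_matrix([([], gts, np.array([1]))])
    assert m[3, 1] == 1 and m.sum() == 1


def test_confusion_matches_brute_force_on_random_case(rng):
    per_image = _per_image_case(rng, n_images=4, max_gt=5)
    got = confusion_matrix(per_image, 0.25, 0.45)
    ref = brute_force_confusion(per_image, 0.25, 0.45)
    np.testing.assert_array_equal(got, ref)
    # columns over true labels sum to true-instance counts
    counts = np.zeros(3, int)
    for _, _, classes in per_image:
        for c in classes:
            counts[c] += 1
    np.testing.assert_array_equal(got[:, :3].sum(axis=0), counts)


# ---------------------------------------------------------------------------
# FPS
# ---------------------------------------------------------------------------

def test_fps_arithmetic():
    assert FPSReport(2.0, 2.0, 1.0).fps == pytest.approx(200.0)
    assert FPSReport(4.0, 4.0, 2.0).fps == pytest.approx(100.0)
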
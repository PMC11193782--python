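"""IoU-family losses: frozen worked examples, invariances, gradients and
the composite detection loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melondet.autograd import Tensor
from melondet.head import DetectConfig, EfficientDetect
from melondet.losses import (Box, LossConfig, alpha_ciou_loss,
                             alpha_ciou_loss_t, ciou_loss,
                             classification_loss, detection_loss, dfl_loss,
                             iou, iou_matrix)
from tests.conftest import random_boxes


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def test_iou_worked_examples():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert iou((0, 0, 1, 1), (2, 2, 3, 3)) == 0.0
    # intersection 1, union 7
    assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)
    # degenerate union is defined as 0, not NaN
    assert iou((1, 1, 1, 1), (1, 1, 1, 1)) == 0.0


def test_iou_symmetry_on_random_pairs(rng):
    a = random_boxes(rng, 200)
    b = random_boxes(rng, 200)
    for i in range(200):
        assert iou(a[i], b[i]) == pytest.approx(iou(b[i], a[i]))
        assert 0.0 <= iou(a[i], b[i]) <= 1.0


def test_box_conversions():
    box = Box.from_center(5, 5, 4, 2)
    assert (box.x1, box.y1, box.x2, box.y2) == (3, 4, 7, 6)
    assert box.to_center() == (5, 5, 4, 2)
    with pytest.raises(ValueError):
        Box(2, 0, 1, 1)


# ---------------------------------------------------------------------------
# CIoU and the power variant
# ---------------------------------------------------------------------------

def test_ciou_identical_boxes_is_zero():
    assert ciou_loss((0, 0, 4, 2), (0, 0, 4, 2)) == pytest.approx(0.0, abs=1e-6)


def test_ciou_aspect_term_vanishes_for_equal_ratios():
    # same w/h ratio: arctan arguments equal, so v = 0 and the loss is
    # exactly 1 - IoU + rho^2/c^2 (centres (1,1) and (12,12), enclosing
    # box (0,0,14,14))
    pred, gt = (0, 0, 2, 2), (10, 10, 14, 14)
    v_free = ciou_loss(pred, gt)
    expected = 1 - iou(pred, gt) + (11 ** 2 + 11 ** 2) / (14 ** 2 + 14 ** 2)
    assert v_free == pytest.approx(expected, abs=1e-6)


def test_ciou_worked_example():
    # IoU = 1/7, centre distance^2 = 2, enclosing diagonal^2 = 18, v = 0:
    # 1 - 1/7 + 2/18 = 61/63 (confirmed by independent hand computation)
    assert ciou_loss((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(61 / 63)


def test_ciou_degenerate_pair_raises():
    with pytest.raises(ValueError):
        ciou_loss((1, 1, 1, 1), (1, 1, 1, 1))


def test_alpha_one_reduces_to_ciou_over_1000_random_pairs(rng):
    preds = random_boxes(rng, 1000)
    gts = random_boxes(rng, 1000)
    cfg1 = LossConfig(alpha=1.0)
    for p, g in zip(preds, gts):
        assert alpha_ciou_loss(p, g, cfg1) == pytest.approx(
            ciou_loss(p, g), rel=1e-9, abs=1e-9)


def test_alpha_ciou_concentric_same_aspect():
    # concentric, same aspect, IoU = 0.5: only the IoU power term remains
    gt = (0, 0, 4, 4)
    s = np.sqrt(0.5) * 4
    o = (4 - s) / 2
    pred = (o, o, o + s, o + s)
    assert iou(pred, gt) == pytest.approx(0.5)
    assert alpha_ciou_loss(pred, gt, LossConfig(alpha=3.0)) \
        == pytest.approx(1 - 0.125, abs=1e-6)


def test_alpha_ciou_zero_at_match_for_any_alpha():
    for a in (0.5, 1.0, 2.0, 3.0):
        assert alpha_ciou_loss((1, 2, 5, 9), (1, 2, 5, 9),
                               LossConfig(alpha=a)) == pytest.approx(0, abs=1e-5)


def test_alpha_must_be_positive():
    with pytest.raises(ValueError):
        LossConfig(alpha=0.0)
    with pytest.raises(ValueError):
        alpha_ciou_loss_t(Tensor(np.zeros((1, 4))), np.zeros((1, 4)), alpha=-1)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.tuples(*[st.floats(-50, 50) for _ in range(4)]),
       st.tuples(*[st.floats(-50, 50) for _ in range(4)]),
       st.floats(-30, 30), st.floats(0.1, 20))
def test_iou_losses_invariant_under_translation_and_scaling(p, g, shift, scale):
    def mk(t):
        x1, y1, x2, y2 = t
        return (min(x1, x2), min(y1, y2), max(x1, x2) + 1, max(y1, y2) + 1)

    def transform(t):
        return tuple(scale * (v + shift) for v in t)

    p, g = mk(p), mk(g)
    assert iou(transform(p), transform(g)) == pytest.approx(iou(p, g),
                                                            abs=1e-6)
    assert ciou_loss(transform(p), transform(g)) == pytest.approx(
        ciou_loss(p, g), rel=1e-4, abs=1e-6)
    assert alpha_ciou_loss(transform(p), transform(g)) == pytest.approx(
        alpha_ciou_loss(p, g), rel=1e-4, abs=1e-6)


def test_ciou_dominates_one_minus_iou(rng):
    preds, gts = random_boxes(rng, 300), random_boxes(rng, 300)
    for p, g in zip(preds, gts):
        assert ciou_loss(p, g) >= 1 - iou(p, g) >= 0


def test_tensor_and_scalar_alpha_ciou_agree(rng):
    preds, gts = random_boxes(rng, 64), random_boxes(rng, 64)
    out = alpha_ciou_loss_t(Tensor(preds.astype(np.float32)),
                            gts.astype(np.float32), alpha=3.0)
    ref = [alpha_ciou_loss(p, g) for p, g in zip(preds, gts)]
    np.testing.assert_allclose(out.data, ref, rtol=2e-3, atol=2e-3)


def test_alpha_ciou_translation_gradient_vanishes_at_match(rng):
    # at an exact match the loss sits at a kink of the IoU surface: the
    # one-sided corner derivatives do not cancel individually, but any
    # rigid translation of the predicted box leaves the loss stationary
    boxes = random_boxes(rng, 16).astype(np.float32)
    pred = Tensor(boxes.copy(), requires_grad=True)
    alpha_ciou_loss_t(pred, boxes, alpha=3.0).sum().backward()
    np.testing.assert_allclose(pred.grad[:, 0] + pred.grad[:, 2], 0.0,
                               atol=1e-4)
    np.testing.assert_allclose(pred.grad[:, 1] + pred.grad[:, 3], 0.0,
                               atol=1e-4)


# ---------------------------------------------------------------------------
# DFL and BCE
# ---------------------------------------------------------------------------

def test_dfl_cases():
    one_hot = np.full(16, -1e4)
    one_hot[7] = 1e4
    assert dfl_loss(one_hot, 7.0) == pytest.approx(0.0, abs=1e-6)
    assert dfl_loss(np.zeros(16), 7.5) == pytest.approx(np.log(16))
    # fractional target interpolates the two bracketing bins
    logits = np.arange(16, dtype=float) * 0.1
    lp = logits - logits.max()
    lp = lp - np.log(np.exp(lp).sum())
    assert dfl_loss(logits, 7.3) == pytest.approx(-0.7 * lp[7] - 0.3 * lp[8])
    with pytest.raises(ValueError):
        dfl_loss(np.zeros(16), 15.5)


def test_classification_loss_cases():
    assert classification_loss([0.0, 0.0], [1.0, 0.0]) \
        == pytest.approx(np.log(2))
    assert classification_loss([0.0], [0.5]) == pytest.approx(np.log(2))
    assert classification_loss([40.0], [1.0]) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        classification_loss([0.0, 0.0], [1.0])
    with pytest.raises(ValueError):
        classification_loss([0.0], [1.5])


# ---------------------------------------------------------------------------
# composite detection loss
# ---------------------------------------------------------------------------

def _head_outputs(rng, cfg, img=64, batch=1, scale=0.1):
    head = EfficientDetect(cfg, rng=rng)
    feats = [Tensor(rng.normal(size=(batch, c, img // s, img // s))
                    .astype(np.float32) * scale)
             for c, s in zip(cfg.level_channels, cfg.strides)]
    return head, feats


def test_detection_loss_without_ground_truth_has_no_box_terms(rng):
    cfg = DetectConfig(nc=3)
    head, feats = _head_outputs(rng, cfg)
    outputs = head(feats)
    total, box, cls, dfl = detection_loss(outputs, [(np.zeros((0, 4)),
                                                     np.zeros(0))])
    assert box == 0.0 and dfl == 0.0
    assert cls > 0.0 and float(total.data) == pytest.approx(0.5 * cls)


def test_detection_loss_decreases_over_gradient_steps(rng):
    from melondet.train import SGD

    cfg = DetectConfig(nc=3)
    head, feats = _head_outputs(rng, cfg, scale=0.5)
    gt = ([np.array([[8.0, 8.0, 40.0, 40.0]]), np.array([1])],)
    opt = SGD(head.parameters(), lr=0.5, momentum=0.9)
    losses = []
    for _ in range(20):
        outputs = head(feats)
        total, *_ = detection_loss(outputs, gt)
        opt.zero_grad()
        total.backward()
        opt.step()
        losses.append(float(total.data))
    assert losses[-1] < losses[0]
    assert np.isfinite(losses).all() and losses[0] > 0
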
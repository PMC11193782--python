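"""Detection heads, anchor-free decoding and non-maximum suppression.

Two heads over the three pyramid levels (strides 8/16/32):

* :class:`EfficientDetect` — per level, one *shared* stem (partial 3x3
  convolution at ratio 1/4 followed by a 1x1 conv with batch norm and
  SiLU) feeds two parallel 1x1 projections: ``nc`` class logits and
  ``4 * reg_max`` box-side distribution logits.  Sharing the stem between
  the classification and regression branches is what makes the head
  cheap; stems are *not* shared across levels (channel counts differ).
* :class:`BaselineDetect` — the reference decoupled head for comparison:
  per level and per branch, two 3x3 convs then a 1x1 projection.

Boxes are decoded anchor-free: each location predicts a discrete
distribution over ``reg_max`` bins for its left/top/right/bottom
distances; the offset is the distribution's softmax expectation, scaled
by the level stride.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, no_grad
from .blocks import ConvBNSiLU, PConv


@dataclass
class DetectConfig:
    nc: int = 3
    level_channels: tuple[int, ...] = (64, 128, 256)
    strides: tuple[int, ...] = (8, 16, 32)
    reg_max: int = 16
    conf_threshold: float = 0.25
    nms_iou_threshold: float = 0.65

    def __post_init__(self):
        if len(self.level_channels) != 3 or len(self.strides) != 3:
            raise ValueError("exactly three pyramid levels are expected")
        if list(self.strides) != sorted(self.strides):
            raise ValueError("strides must be strictly increasing")
        if self.nc < 1:
            raise ValueError("nc must be >= 1")


@dataclass
class Detection:
    """One decoded detection: corner-form box in input-image pixels."""

    box: np.ndarray  # (4,) x1, y1, x2, y2
    class_id: int
    score: float


def _cls_bias_init(nc: int, stride: int, img_size: int = 640) -> float:
    # prior so that roughly 5 objects per image are expected at start
    return float(np.log(5.0 / nc / (img_size / stride) ** 2))


class EfficientDetect(nn.Module):
    """Shared-stem head: PConv + 1x1 stem, then per-branch 1x1 projections."""

    def __init__(self, cfg: DetectConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or DetectConfig()
        self.stems = nn.ModuleList()
        self.cls_preds = nn.ModuleList()
        self.reg_preds = nn.ModuleList()
        for c, s in zip(self.cfg.level_channels, self.cfg.strides):
            self.stems.append(nn.Sequential(
                PConv(c, 0.25, 3, rng=rng),
                ConvBNSiLU(c, c, 1, rng=rng)))
            cls = nn.Conv2d(c, self.cfg.nc, 1, bias=True, rng=rng)
            cls.bias.data[:] = _cls_bias_init(self.cfg.nc, s)
            self.cls_preds.append(cls)
            reg = nn.Conv2d(c, 4 * self.cfg.reg_max, 1, bias=True, rng=rng)
            reg.bias.data[:] = 1.0
            self.reg_preds.append(reg)

    def forward(self, features: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        if len(features) != 3:
            raise ValueError("expected three feature maps")
        outputs = []
        for x, stem, cls, reg in zip(features, self.stems, self.cls_preds,
                                     self.reg_preds):
            h = stem(x)
            outputs.append((cls(h), reg(h)))
        return outputs


class BaselineDetect(nn.Module):
    """Reference decoupled head: two 3x3 convs + 1x1 projection per branch."""

    def __init__(self, cfg: DetectConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or DetectConfig()
        ch = self.cfg.level_channels
        c2 = max(16, ch[0] // 4, self.cfg.reg_max * 4)
        c3 = max(ch[0], min(self.cfg.nc, 100))
        self.reg_branches = nn.ModuleList()
        self.cls_branches = nn.ModuleList()
        for c, s in zip(ch, self.cfg.strides):
            reg_proj = nn.Conv2d(c2, 4 * self.cfg.reg_max, 1, bias=True, rng=rng)
            reg_proj.bias.data[:] = 1.0
            self.reg_branches.append(nn.Sequential(
                ConvBNSiLU(c, c2, 3, rng=rng), ConvBNSiLU(c2, c2, 3, rng=rng),
                reg_proj))
            cls_proj = nn.Conv2d(c3, self.cfg.nc, 1, bias=True, rng=rng)
            cls_proj.bias.data[:] = _cls_bias_init(self.cfg.nc, s)
            self.cls_branches.append(nn.Sequential(
                ConvBNSiLU(c, c3, 3, rng=rng), ConvBNSiLU(c3, c3, 3, rng=rng),
                cls_proj))

    def forward(self, features: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        if len(features) != 3:
            raise ValueError("expected three feature maps")
        return [(cls(x), reg(x))
                for x, cls, reg in zip(features, self.cls_branches,
                                       self.reg_branches)]


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def make_anchor_points(level_shapes: list[tuple[int, int]],
                       strides: tuple[int, ...],
                       offset: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Grid-cell centres for each level, in stride units.

    Returns (points (N,2), stride_per_point (N,)).
    """
    points, strd = [], []
    for (h, w), s in zip(level_shapes, strides):
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts = np.stack([xs.ravel() + offset, ys.ravel() + offset], axis=1)
        points.append(pts)
        strd.append(np.full(h * w, s))
    return (np.concatenate(points).astype(np.float32),
            np.concatenate(strd).astype(np.float32))


def distribution_expectation(reg_logits: np.ndarray, reg_max: int) -> np.ndarray:
    """Softmax expectation over the reg_max bins (last axis groups of bins).

    reg_logits: (..., 4*reg_max) -> offsets (..., 4) in stride units.
    """
    shaped = reg_logits.reshape(*reg_logits.shape[:-1], 4, reg_max)
    shifted = shaped - shaped.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs @ np.arange(reg_max, dtype=np.float32)


def decode_predictions(outputs: list[tuple[Tensor, Tensor]],
                       cfg: DetectConfig) -> list[list[Detection]]:
    """Turn per-level head outputs into per-image detection lists.

    Box = anchor point -/+ expected left/top/right/bottom offsets, scaled
    by the level stride; score = sigmoid class logit; candidates below
    ``cfg.conf_threshold`` are dropped.  No suppression is applied here.
    """
    with no_grad():
        level_shapes = [(c.shape[2], c.shape[3]) for c, _ in outputs]
        points, strd = make_anchor_points(level_shapes, cfg.strides)
        batch = outputs[0][0].shape[0]
        cls_flat, reg_flat = [], []
        for cls, reg in outputs:
            b, nc, h, w = cls.shape
            cls_flat.append(cls.data.reshape(b, nc, h * w).transpose(0, 2, 1))
            reg_flat.append(reg.data.reshape(b, 4 * cfg.reg_max, h * w)
                            .transpose(0, 2, 1))
        cls_all = np.concatenate(cls_flat, axis=1)  # (B, N, nc)
        reg_all = np.concatenate(reg_flat, axis=1)  # (B, N, 4*reg_max)
        from .autograd import _sigmoid
        scores = _sigmoid(cls_all)
        ltrb = distribution_expectation(reg_all, cfg.reg_max)
        x1y1 = points[None] - ltrb[..., :2]
        x2y2 = points[None] + ltrb[..., 2:]
        boxes = np.concatenate([x1y1, x2y2], axis=-1) * strd[None, :, None]
        results: list[list[Detection]] = []
        for i in range(batch):
            best_cls = scores[i].argmax(axis=1)
            best_score = scores[i].max(axis=1)
            keep = best_score >= cfg.conf_threshold
            results.append([
                Detection(boxes[i, j].copy(), int(best_cls[j]),
                          float(best_score[j]))
                for j in np.flatnonzero(keep)])
        return results


def nms(candidates: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy class-wise suppression.

    Iteratively keeps the highest-scoring candidate and removes same-class
    candidates overlapping it above the threshold.  Ties in score are
    broken by lower candidate index, making the result deterministic.
    """
    from .losses import iou_matrix

    if not candidates:
        return []
    order = sorted(range(len(candidates)),
                   key=lambda i: (-candidates[i].score, i))
    boxes = np.stack([c.box for c in candidates])
    ious = iou_matrix(boxes, boxes)
    kept: list[int] = []
    suppressed = np.zeros(len(candidates), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        same = np.array([candidates[j].class_id == candidates[i].class_id
                         for j in range(len(candidates))])
        suppressed |= same & (ious[i] > iou_threshold)
        suppressed[i] = True
    return [candidates[i] for i in kept]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def detections_to_yolo_lines(dets: list[Detection], img_w: int,
                             img_h: int) -> str:
    """Render detections as 'class cx cy w h conf' normalised text lines."""
    lines = []
    for d in dets:
        x1, y1, x2, y2 = d.box
        cx, cy = (x1 + x2) / 2 / img_w, (y1 + y2) / 2 / img_h
        w, h = (x2 - x1) / img_w, (y2 - y1) / img_h
        lines.append(f"{d.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f} "
                     f"{d.score:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def detections_to_json(dets: list[Detection]) -> str:
    return json.dumps([
        {"box": [float(v) for v in d.box], "class_id": d.class_id,
         "score": d.score} for d in dets], indent=2)
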
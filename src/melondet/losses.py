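"""Bounding-box geometry and the detector's composite loss.

The box-regression loss family:

``L_CIoU    = 1 - IoU + rho^2/c^2 + theta * v``
``L_a-CIoU  = 1 - IoU^a + (rho^2/c^2)^a + (theta * v)^a``

where ``rho`` is the distance between box centres, ``c`` the diagonal of
the smallest enclosing box, ``v = 4/pi^2 (arctan(w_gt/h_gt) -
arctan(w/h))^2`` the aspect-ratio term, and ``theta = v / ((1 - IoU) + v)``
its weight, treated as a constant with respect to the gradient (the
standard complete-IoU convention).  The power ``a`` (default 3) sharpens
gradients for already-well-overlapping boxes; at ``a = 1`` the loss
reduces exactly to CIoU.

Classification uses binary cross-entropy with logits; box-side offsets
additionally carry a distribution focal loss (cross-entropy against the
two integer bins bracketing the continuous target, linearly weighted).
Positive anchors are chosen by a task-aligned assigner
(``score^0.5 * IoU^6``, top-10 per target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concatenate, no_grad, where

EPS = 1e-7


@dataclass
class Box:
    """Axis-aligned box in corner form (image-plane coordinates)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError("box corners must satisfy x2 >= x1, y2 >= y1")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Box":
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    def to_center(self) -> tuple[float, float, float, float]:
        return ((self.x1 + self.x2) / 2, (self.y1 + self.y2) / 2,
                self.width, self.height)

    @classmethod
    def from_normalized(cls, cx, cy, w, h, img_w: int, img_h: int) -> "Box":
        return cls.from_center(cx * img_w, cy * img_h, w * img_w, h * img_h)


@dataclass
class LossConfig:
    alpha: float = 3.0
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5
    reg_max: int = 16
    tal_topk: int = 10
    tal_alpha: float = 0.5
    tal_beta: float = 6.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if min(self.box_weight, self.cls_weight, self.dfl_weight) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.reg_max < 2:
            raise ValueError("reg_max must be >= 2")


def _coerce(box) -> np.ndarray:
    if isinstance(box, Box):
        return box.to_array()
    arr = np.asarray(box, dtype=np.float64)
    if arr.shape != (4,):
        raise ValueError("expected a Box or a length-4 corner array")
    if arr[2] < arr[0] or arr[3] < arr[1]:
        raise ValueError("box corners must satisfy x2 >= x1, y2 >= y1")
    return arr


# ---------------------------------------------------------------------------
# scalar geometry
# ---------------------------------------------------------------------------

def iou(a, b) -> float:
    """Intersection over union of two boxes; 0 for a degenerate union."""
    a, b = _coerce(a), _coerce(b)
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        inter = 0.0
    else:
        inter = iw * ih
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    if union <= 0:
        return 0.0
    return float(inter / union)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) corner-form arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, EPS), 0.0)


def ciou_loss(pred, gt) -> float:
    """Complete-IoU loss between two boxes (scalar form)."""
    return alpha_ciou_loss(pred, gt, LossConfig(alpha=1.0))


def alpha_ciou_loss(pred, gt, cfg: LossConfig | None = None) -> float:
    """Power-CIoU loss; reduces to plain CIoU at alpha = 1."""
    cfg = cfg or LossConfig()
    p, g = _coerce(pred), _coerce(gt)
    a = cfg.alpha
    overlap = iou(p, g)
    ex1, ey1 = min(p[0], g[0]), min(p[1], g[1])
    ex2, ey2 = max(p[2], g[2]), max(p[3], g[3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    if c2 <= 0:
        raise ValueError("degenerate box pair: zero-size enclosing box")
    pcx, pcy = (p[0] + p[2]) / 2, (p[1] + p[3]) / 2
    gcx, gcy = (g[0] + g[2]) / 2, (g[1] + g[3]) / 2
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    pw, ph = max(p[2] - p[0], EPS), max(p[3] - p[1], EPS)
    gw, gh = max(g[2] - g[0], EPS), max(g[3] - g[1], EPS)
    v = 4.0 / np.pi ** 2 * (np.arctan(gw / gh) - np.arctan(pw / ph)) ** 2
    theta = v / ((1.0 - overlap) + v + EPS)
    return float((1.0 - overlap ** a) + (rho2 / c2) ** a + (theta * v) ** a)


# ---------------------------------------------------------------------------
# tensorised geometry (training path)
# ---------------------------------------------------------------------------

def _abs_t(x: Tensor) -> Tensor:
    return where(x.data >= 0, x, -x)


def alpha_ciou_loss_t(pred: Tensor, gt: np.ndarray, alpha: float = 3.0) -> Tensor:
    """Vectorised power-CIoU over (N, 4) corner-form boxes (autograd)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    gt = np.asarray(gt, dtype=np.float32).reshape(-1, 4)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = (Tensor(gt[:, i]) for i in range(4))
    from .autograd import maximum, minimum
    iw = (minimum(px2, gx2) - maximum(px1, gx1)).clip(0, np.inf)
    ih = (minimum(py2, gy2) - maximum(py1, gy1)).clip(0, np.inf)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter + EPS
    ov = inter / union
    ex1, ey1 = minimum(px1, gx1), minimum(py1, gy1)
    ex2, ey2 = maximum(px2, gx2), maximum(py2, gy2)
    c2 = (ex2 - ex1) ** 2.0 + (ey2 - ey1) ** 2.0 + EPS
    rho2 = (((px1 + px2) - (gx1 + gx2)) ** 2.0
            + ((py1 + py2) - (gy1 + gy2)) ** 2.0) * 0.25
    pw = (px2 - px1) + EPS
    ph = (py2 - py1) + EPS
    gw = (gx2 - gx1).data + EPS
    gh = (gy2 - gy1).data + EPS
    v = (4.0 / np.pi ** 2) * (Tensor(np.arctan(gw / gh)) - (pw / ph).arctan()) ** 2.0
    theta = Tensor(v.data / ((1.0 - ov.data) + v.data + EPS))  # no gradient
    return ((1.0 - ov ** alpha) + (rho2 / c2 + EPS) ** alpha
            + (theta * v + EPS) ** alpha)


# ---------------------------------------------------------------------------
# distribution focal loss and classification loss
# ---------------------------------------------------------------------------

def dfl_loss(dist_logits, target_offset: float, reg_max: int | None = None) -> float:
    """Scalar distribution focal loss for one box side."""
    logits = np.asarray(dist_logits, dtype=np.float64).reshape(-1)
    reg_max = reg_max or logits.size
    if logits.size != reg_max:
        raise ValueError("logit vector length must equal reg_max")
    if not (0 <= target_offset <= reg_max - 1):
        raise ValueError("target offset outside bin range")
    shifted = logits - logits.max()
    log_probs = shifted - np.log(np.exp(shifted).sum())
    lo = int(np.floor(target_offset))
    hi = lo + 1
    w_hi = target_offset - lo
    if hi > reg_max - 1:
        hi, w_hi = lo, 0.0
    return float(-(1.0 - w_hi) * log_probs[lo] - w_hi * log_probs[hi])


def _bce_with_logits_t(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy with logits."""
    t = Tensor(np.asarray(targets, dtype=np.float32))
    return (logits.relu() - logits * t
            + (1.0 + (-_abs_t(logits)).exp()).log())


def classification_loss(pred_logits, targets, reduction: str = "mean") -> float:
    """Binary cross-entropy with logits over matching-shape arrays."""
    logits = np.asarray(pred_logits, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if logits.shape != t.shape:
        raise ValueError("shape mismatch between logits and targets")
    if t.size and (t.min() < 0 or t.max() > 1):
        raise ValueError("targets must lie in [0, 1]")
    elem = np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits)))
    if reduction == "mean":
        return float(elem.mean())
    if reduction == "sum":
        return float(elem.sum())
    raise ValueError("reduction must be 'mean' or 'sum'")


# ---------------------------------------------------------------------------
# task-aligned assignment
# ---------------------------------------------------------------------------

def task_aligned_assign(scores: np.ndarray, boxes: np.ndarray,
                        points: np.ndarray, gt_boxes: np.ndarray,
                        gt_classes: np.ndarray, cfg: LossConfig
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign anchors to ground-truth boxes for one image.

    Returns (fg_mask (N,), assigned_gt (N,), target_scores (N, nc_dim is
    left to the caller: here per-anchor scalar alignment weight and class)).
    Specifically: fg_mask bool, gt index per anchor, and the normalised
    alignment weight per anchor.
    """
    n_anchors = scores.shape[0]
    n_gt = gt_boxes.shape[0]
    if n_gt == 0:
        return (np.zeros(n_anchors, bool), np.zeros(n_anchors, np.int64),
                np.zeros(n_anchors, np.float32))
    cls_score = scores[:, gt_classes]                      # (N, M)
    overlaps = iou_matrix(boxes, gt_boxes)                 # (N, M)
    metric = (np.maximum(cls_score, 0) ** cfg.tal_alpha
              * overlaps ** cfg.tal_beta)
    inside = ((points[:, None, 0] > gt_boxes[None, :, 0])
              & (points[:, None, 0] < gt_boxes[None, :, 2])
              & (points[:, None, 1] > gt_boxes[None, :, 1])
              & (points[:, None, 1] < gt_boxes[None, :, 3]))
    metric = np.where(inside, metric, 0.0)
    mask_pos = np.zeros_like(metric, dtype=bool)
    k = min(cfg.tal_topk, n_anchors)
    for m in range(n_gt):
        cand = np.argpartition(-metric[:, m], k - 1)[:k]
        cand = cand[metric[cand, m] > 0]
        mask_pos[cand, m] = True
    # an anchor serving several targets keeps the one it overlaps most
    multi = mask_pos.sum(axis=1) > 1
    if multi.any():
        best = overlaps[multi].argmax(axis=1)
        mask_pos[multi] = False
        mask_pos[np.flatnonzero(multi), best] = True
    fg_mask = mask_pos.any(axis=1)
    assigned = mask_pos.argmax(axis=1)
    # normalised alignment weight (task-aligned soft label)
    pos_metric = np.where(mask_pos, metric, 0.0)
    pos_overlap = np.where(mask_pos, overlaps, 0.0)
    per_gt_metric = pos_metric.max(axis=0) + EPS
    per_gt_overlap = pos_overlap.max(axis=0)
    norm = (pos_metric * per_gt_overlap[None, :]
            / per_gt_metric[None, :]).max(axis=1)
    return fg_mask, assigned, norm.astype(np.float32)


# ---------------------------------------------------------------------------
# full detection loss
# ---------------------------------------------------------------------------

def _flatten_outputs(outputs, reg_max: int):
    cls_flat, reg_flat, shapes = [], [], []
    for cls, reg in outputs:
        b, nc, h, w = cls.shape
        shapes.append((h, w))
        cls_flat.append(cls.reshape(b, nc, h * w).transpose(0, 2, 1))
        reg_flat.append(reg.reshape(b, 4 * reg_max, h * w).transpose(0, 2, 1))
    return (concatenate(cls_flat, axis=1), concatenate(reg_flat, axis=1),
            shapes)


def detection_loss(outputs, ground_truth, cfg: LossConfig | None = None,
                   strides: tuple[int, ...] = (8, 16, 32)
                   ) -> tuple[Tensor, float, float, float]:
    """Composite detection loss over a batch.

    ``outputs``: per-level (cls_logits, reg_logits) tensor pairs from a
    head.  ``ground_truth``: per image, a pair (boxes (M,4) corner-form in
    input pixels, classes (M,)).  Returns (total loss tensor, box term,
    cls term, dfl term) — the floats are the unweighted means for logging.
    """
    from .head import make_anchor_points

    cfg = cfg or LossConfig()
    nc = outputs[0][0].shape[1]
    pred_scores, pred_dist, shapes = _flatten_outputs(outputs, cfg.reg_max)
    batch, n_anchors = pred_scores.shape[0], pred_scores.shape[1]
    points, strd = make_anchor_points(shapes, strides)
    proj = Tensor(np.arange(cfg.reg_max, dtype=np.float32).reshape(-1, 1))

    # decode boxes in stride units, keeping the graph
    probs = pred_dist.reshape(batch, n_anchors, 4, cfg.reg_max).softmax(axis=-1)
    ltrb = (probs.reshape(batch * n_anchors * 4, cfg.reg_max) @ proj)
    ltrb = ltrb.reshape(batch, n_anchors, 4)
    pts = Tensor(points)
    x1y1 = pts - ltrb[:, :, :2]
    x2y2 = pts + ltrb[:, :, 2:]
    pred_boxes = concatenate([x1y1, x2y2], axis=2)  # stride units

    target_scores = np.zeros((batch, n_anchors, nc), dtype=np.float32)
    fg_masks = np.zeros((batch, n_anchors), dtype=bool)
    tgt_boxes = np.zeros((batch, n_anchors, 4), dtype=np.float32)
    with no_grad():
        for i, (gt_boxes, gt_classes) in enumerate(ground_truth):
            gt_boxes = np.asarray(gt_boxes, dtype=np.float32).reshape(-1, 4)
            gt_classes = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
            from .autograd import _sigmoid
            sig = _sigmoid(pred_scores.data[i])
            boxes_px = pred_boxes.data[i] * strd[:, None]
            fg, assigned, weight = task_aligned_assign(
                sig, boxes_px, points * strd[:, None], gt_boxes, gt_classes,
                cfg)
            fg_masks[i] = fg
            if fg.any():
                target_scores[i, fg, gt_classes[assigned[fg]]] = weight[fg]
                tgt_boxes[i, fg] = gt_boxes[assigned[fg]] / strd[fg, None]

    score_sum = max(float(target_scores.sum()), 1.0)
    cls_elem = _bce_with_logits_t(pred_scores, target_scores)
    cls_loss = cls_elem.sum() * (1.0 / score_sum)

    n_fg = int(fg_masks.sum())
    if n_fg:
        b_idx, a_idx = np.nonzero(fg_masks)
        pb = pred_boxes[b_idx, a_idx]
        tb = tgt_boxes[b_idx, a_idx]
        w = target_scores[b_idx, a_idx].sum(axis=1)
        box_elem = alpha_ciou_loss_t(pb, tb, cfg.alpha)
        box_loss = (box_elem * Tensor(w)).sum() * (1.0 / score_sum)
        # distribution focal loss over the four sides
        pts_fg = points[a_idx]
        ltrb_t = np.concatenate([pts_fg - tb[:, :2], tb[:, 2:] - pts_fg],
                                axis=1)
        ltrb_t = np.clip(ltrb_t, 0, cfg.reg_max - 1 - 0.01)
        logits_fg = pred_dist[b_idx, a_idx].reshape(n_fg * 4, cfg.reg_max)
        lo = np.floor(ltrb_t.reshape(-1)).astype(np.int64)
        hi = lo + 1
        w_hi = (ltrb_t.reshape(-1) - lo).astype(np.float32)
        log_probs = logits_fg.log_softmax(axis=1)
        rows = np.arange(n_fg * 4)
        ce = -(log_probs[rows, lo] * Tensor(1.0 - w_hi)
               + log_probs[rows, hi] * Tensor(w_hi))
        dfl = (ce.reshape(n_fg, 4).mean(axis=1) * Tensor(w)).sum() \
            * (1.0 / score_sum)
    else:
        box_loss = Tensor(0.0)
        dfl = Tensor(0.0)

    total = (cfg.box_weight * box_loss + cfg.cls_weight * cls_loss
             + cfg.dfl_weight * dfl)
    return total, float(box_loss.data), float(cls_loss.data), float(dfl.data)
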
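"""Detection metrics: precision/recall, average precision, confusion
matrix and frame-rate measurement.

Average precision realises the area under the precision-recall curve by
101-point interpolation (precision at recall r is the maximum precision
achieved at any recall >= r, sampled at r = 0, 0.01, ..., 1); mAP@0.5 is
the class mean at IoU 0.5 and mAP@0.5:0.95 additionally averages the IoU
threshold over 0.50 to 0.95 in steps of 0.05.  Matching is greedy and
one-to-one: detections are visited in descending confidence and claim
their best-IoU unmatched same-class ground truth above the threshold.

Frame rate is the reciprocal of the summed per-image means of the three
pipeline stages (pre-processing, network inference, suppression); it is
hardware-bound and reported for information only.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .data import CLASS_NAMES, ImageRecord
from .head import Detection
from .losses import iou_matrix

N_CLASSES = len(CLASS_NAMES)
IOU_SWEEP = np.arange(0.5, 0.96, 0.05).round(2)


# ---------------------------------------------------------------------------
# matching and counting
# ---------------------------------------------------------------------------

def match_detections(dets: list[Detection], gt_boxes: np.ndarray,
                     gt_classes: np.ndarray, iou_threshold: float = 0.5
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching.

    ``dets`` must be sorted by descending confidence.  Returns
    (tp flags per detection, matched-gt index per detection or -1);
    ground truths left unmatched are the false negatives.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    gt_classes = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
    tp = np.zeros(len(dets), dtype=bool)
    matched_gt = np.full(len(dets), -1, dtype=np.int64)
    taken = np.zeros(len(gt_boxes), dtype=bool)
    if len(dets) and len(gt_boxes):
        ious = iou_matrix(np.stack([d.box for d in dets]), gt_boxes)
        for i, det in enumerate(dets):
            cand = np.flatnonzero((gt_classes == det.class_id) & ~taken
                                  & (ious[i] > iou_threshold))
            if cand.size:
                j = cand[np.argmax(ious[i, cand])]
                taken[j] = True
                tp[i] = True
                matched_gt[i] = j
    return tp, matched_gt


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); the empty ratio 0/0 is defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def average_precision(scores: np.ndarray, is_tp: np.ndarray,
                      n_gt: int) -> float:
    """101-point interpolated AP from scored, TP-labelled detections."""
    if n_gt == 0:
        return float("nan")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    tp = np.asarray(is_tp, bool)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # monotone envelope, then sample at 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    points = np.linspace(0, 1, 101)
    # the tiny slack keeps float recall values equal to a sample point
    # (e.g. 0.3000000000004) on the correct side
    idx = np.searchsorted(recall, points - 1e-9, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def _class_ap(per_image: list[tuple[list[Detection], np.ndarray, np.ndarray]],
              class_id: int, iou_threshold: float) -> tuple[float, int]:
    scores, flags = [], []
    n_gt = 0
    for dets, gt_boxes, gt_classes in per_image:
        gt_classes = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
        n_gt += int((gt_classes == class_id).sum())
        cls_dets = sorted([d for d in dets if d.class_id == class_id],
                          key=lambda d: -d.score)
        tp, _ = match_detections(cls_dets, gt_boxes, gt_classes,
                                 iou_threshold)
        scores.extend(d.score for d in cls_dets)
        flags.extend(tp.tolist())
    return average_precision(np.array(scores), np.array(flags), n_gt), n_gt


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def confusion_matrix(per_image, conf_threshold: float = 0.25,
                     iou_threshold: float = 0.45) -> np.ndarray:
    """(nc+1) x (nc+1) matrix; rows are predicted labels, columns true
    labels, with the extra index standing for background (missed or
    spurious).  Matching here is class-agnostic so that confusions
    between classes are visible."""
    m = np.zeros((N_CLASSES + 1, N_CLASSES + 1), dtype=np.int64)
    for dets, gt_boxes, gt_classes in per_image:
        gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
        gt_classes = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
        dets = sorted([d for d in dets if d.score >= conf_threshold],
                      key=lambda d: -d.score)
        taken = np.zeros(len(gt_boxes), dtype=bool)
        if dets and len(gt_boxes):
            ious = iou_matrix(np.stack([d.box for d in dets]), gt_boxes)
        for i, det in enumerate(dets):
            j = -1
            if len(gt_boxes):
                cand = np.flatnonzero(~taken & (ious[i] > iou_threshold))
                if cand.size:
                    j = cand[np.argmax(ious[i, cand])]
                    taken[j] = True
            if j >= 0:
                m[det.class_id, gt_classes[j]] += 1
            else:
                m[det.class_id, N_CLASSES] += 1
        for j in np.flatnonzero(~taken):
            m[N_CLASSES, gt_classes[j]] += 1
    return m


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    precision: float
    recall: float
    ap50: float
    ap50_95: float
    n_gt: int


@dataclass
class FPSReport:
    t_preprocess_ms: float
    t_inference_ms: float
    t_nms_ms: float

    @property
    def fps(self) -> float:
        total = (self.t_preprocess_ms + self.t_inference_ms
                 + self.t_nms_ms)
        return 1e3 / total if total > 0 else float("inf")


@dataclass
class EvalReport:
    per_class: dict[str, ClassMetrics]
    map50: float
    map50_95: float
    confusion: np.ndarray
    fps: FPSReport | None = None

    def to_json(self) -> str:
        payload = {
            "mAP@0.5": self.map50,
            "mAP@0.5:0.95": self.map50_95,
            "classes": {
                name: {"precision": c.precision, "recall": c.recall,
                       "AP@0.5": c.ap50, "AP@0.5:0.95": c.ap50_95,
                       "n_gt": c.n_gt}
                for name, c in self.per_class.items()},
            "confusion_matrix": self.confusion.tolist(),
        }
        if self.fps is not None:
            payload["fps"] = {
                "t_preprocess_ms": self.fps.t_preprocess_ms,
                "t_inference_ms": self.fps.t_inference_ms,
                "t_nms_ms": self.fps.t_nms_ms,
                "fps": self.fps.fps,
            }
        return json.dumps(payload, indent=2)


def evaluate_detections(per_image, conf_threshold: float = 0.25
                        ) -> EvalReport:
    """Full metric suite over per-image (detections, gt boxes, gt classes).

    Classes with no ground truth anywhere are excluded from the mAP mean
    (their AP is undefined).
    """
    per_class: dict[str, ClassMetrics] = {}
    ap50s, ap5095s = [], []
    for c, name in enumerate(CLASS_NAMES):
        ap50, n_gt = _class_ap(per_image, c, 0.5)
        sweep = [ap50] + [_class_ap(per_image, c, t)[0] for t in IOU_SWEEP[1:]]
        ap5095 = float(np.mean(sweep)) if n_gt else float("nan")
        tp = fp = fn = 0
        for dets, gt_boxes, gt_classes in per_image:
            cls_dets = sorted([d for d in dets if d.class_id == c
                               and d.score >= conf_threshold],
                              key=lambda d: -d.score)
            flags, _ = match_detections(cls_dets, gt_boxes, gt_classes, 0.5)
            tp += int(flags.sum())
            fp += int((~flags).sum())
            gt_cls = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
            fn += int((gt_cls == c).sum()) - int(flags.sum())
        p, r = precision_recall(tp, fp, fn)
        per_class[name] = ClassMetrics(p, r, ap50 if n_gt else float("nan"),
                                       ap5095, n_gt)
        if n_gt:
            ap50s.append(ap50)
            ap5095s.append(ap5095)
    map50 = float(np.mean(ap50s)) if ap50s else float("nan")
    map5095 = float(np.mean(ap5095s)) if ap5095s else float("nan")
    return EvalReport(per_class, map50, map5095,
                      confusion_matrix(per_image, conf_threshold))


def collect_predictions(model, records: list[ImageRecord],
                        conf_threshold: float = 0.001,
                        batch_size: int = 8):
    """Run a detector over records, returning the evaluation triples."""
    per_image = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        batch = np.stack([r.image for r in chunk]).astype(np.float32) / 255.0
        batch = batch.transpose(0, 3, 1, 2)
        dets_batch = model.predict(batch, conf_threshold=conf_threshold)
        for rec, dets in zip(chunk, dets_batch):
            gt_boxes = np.array([a.corners(rec.width, rec.height)
                                 for a in rec.annotations]).reshape(-1, 4)
            gt_classes = np.array([a.class_id for a in rec.annotations],
                                  dtype=np.int64)
            per_image.append((dets, gt_boxes, gt_classes))
    return per_image


def evaluate_model(model, records: list[ImageRecord],
                   conf_threshold: float = 0.25,
                   ap_conf_threshold: float = 0.001) -> EvalReport:
    per_image = collect_predictions(model, records, ap_conf_threshold)
    return evaluate_detections(per_image, conf_threshold)


# ---------------------------------------------------------------------------
# frame rate
# ---------------------------------------------------------------------------

def measure_fps(model, images: list[np.ndarray]) -> FPSReport:
    """Time preprocessing, inference and suppression separately.

    ``images`` are HWC uint8 arrays.  Hardware-bound; informational only.
    """
    if not images:
        raise ValueError("need at least one image")
    from .autograd import Tensor, no_grad
    from .head import decode_predictions, nms

    t_pre = t_inf = t_nms = 0.0
    model.eval()
    with no_grad():
        for img in images:
            t0 = time.perf_counter()
            batch = img.astype(np.float32)[None].transpose(0, 3, 1, 2) / 255.0
            t1 = time.perf_counter()
            outputs = model(Tensor(batch))
            t2 = time.perf_counter()
            raw = decode_predictions(outputs, model.head.cfg)
            nms(raw[0], model.head.cfg.nms_iou_threshold)
            t3 = time.perf_counter()
            t_pre += t1 - t0
            t_inf += t2 - t1
            t_nms += t3 - t2
    n = len(images)
    return FPSReport(t_pre / n * 1e3, t_inf / n * 1e3, t_nms / n * 1e3)
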
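"""Training loop: SGD with momentum, warmup + linear decay, loss logging.

The regime mirrors the study's published settings (SGD, initial learning
rate 0.01, momentum 0.937, weight decay 0.0005, batch 64, 300 epochs,
mosaic augmentation disabled for the last ten epochs) while remaining
fully configurable so the same loop runs at desk scale on synthetic
scenes.  Training is from scratch (no pretrained weights) and
deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .data import Annotation, ImageRecord
from .losses import LossConfig, detection_loss
from .model import DetectionModel, ModelSpec, build_model


@dataclass
class TrainConfig:
    img_size: int = 640
    batch_size: int = 64
    epochs: int = 300
    lr0: float = 0.01
    lrf: float = 0.01          # final LR fraction of lr0 (linear decay)
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: int = 3
    close_mosaic_epochs: int = 10
    mosaic: bool = False
    seed: int = 0
    alpha: float = 3.0         # box-loss power

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr0 < 0:
            raise ValueError("lr0 must be non-negative")
        if self.close_mosaic_epochs > self.epochs:
            raise ValueError("close_mosaic_epochs cannot exceed epochs")


class SGD:
    """Momentum SGD; weight decay applied to weight matrices only."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return [v.copy() for v in self.velocity]

    def load_state(self, state: list[np.ndarray]) -> None:
        for v, s in zip(self.velocity, state):
            v[:] = s


def _lr_at(cfg: TrainConfig, epoch: int, step: int, steps_per_epoch: int
           ) -> float:
    """Linear warmup over the first epochs, then linear decay to lrf*lr0."""
    total = epoch + step / max(steps_per_epoch, 1)
    if cfg.warmup_epochs > 0 and total < cfg.warmup_epochs:
        return cfg.lr0 * total / cfg.warmup_epochs
    frac = (total - cfg.warmup_epochs) / max(cfg.epochs - cfg.warmup_epochs,
                                             1e-9)
    frac = min(frac, 1.0)
    return cfg.lr0 * (1.0 - frac * (1.0 - cfg.lrf))


def _mosaic(records: list[ImageRecord], rng: np.random.Generator
            ) -> ImageRecord:
    """Four-image collage at the records' common size (minimal variant)."""
    picks = [records[i] for i in rng.choice(len(records), 4)]
    size = picks[0].height
    half = size // 2
    canvas = np.zeros((size, size, 3), dtype=np.uint8)
    anns: list[Annotation] = []
    for q, rec in enumerate(picks):
        oy, ox = (q // 2) * half, (q % 2) * half
        small = rec.image[::2, ::2][:half, :half]
        canvas[oy:oy + half, ox:ox + half] = small
        for a in rec.annotations:
            cx, cy = a.cx / 2 + ox / size, a.cy / 2 + oy / size
            w, h = a.w / 2, a.h / 2
            if w * size > 2 and h * size > 2:
                anns.append(Annotation(a.class_id, cx, cy, w, h))
    return ImageRecord(canvas, anns, "mosaic")


def _to_batch(records: list[ImageRecord]) -> tuple[np.ndarray, list]:
    images = np.stack([r.image for r in records]).astype(np.float32) / 255.0
    images = images.transpose(0, 3, 1, 2)
    gts = []
    for r in records:
        boxes = np.array([a.corners(r.width, r.height)
                          for a in r.annotations]).reshape(-1, 4)
        classes = np.array([a.class_id for a in r.annotations], np.int64)
        gts.append((boxes, classes))
    return images, gts


@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)
    checkpoint: str | None = None

    def history_csv(self) -> str:
        if not self.history:
            return ""
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(self.history[0].keys()))
        writer.writeheader()
        writer.writerows(self.history)
        return buf.getvalue()


def save_checkpoint(model: DetectionModel, path: str | Path,
                    optimizer: SGD | None = None, epoch: int = 0) -> None:
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        for i, v in enumerate(optimizer.state()):
            payload[f"optim/{i}"] = v
    payload["epoch"] = np.array(epoch)
    payload["spec_yaml"] = np.frombuffer(
        model.spec.to_yaml().encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path
                    ) -> tuple[DetectionModel, list[np.ndarray] | None, int]:
    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec.from_yaml(bytes(z["spec_yaml"]).decode())
        model = build_model(spec)
        model.load_state_dict({k[len("model/"):]: z[k] for k in z.files
                               if k.startswith("model/")})
        opt_keys = sorted((k for k in z.files if k.startswith("optim/")),
                          key=lambda k: int(k.split("/")[1]))
        opt_state = [z[k] for k in opt_keys] if opt_keys else None
        epoch = int(z["epoch"])
    return model, opt_state, epoch


def train(model: DetectionModel, train_records: list[ImageRecord],
          cfg: TrainConfig, val_records: list[ImageRecord] | None = None,
          log_path: str | Path | None = None,
          checkpoint_path: str | Path | None = None,
          eval_every: int = 0, resume_state=None) -> TrainResult:
    """Run the SGD loop; returns the per-epoch loss/metric history.

    ``eval_every > 0`` computes validation mAP@0.5 every that many epochs
    (and on the final epoch).  The loss trajectory is deterministic for a
    fixed seed on fixed data.
    """
    if not train_records:
        raise ValueError("empty training split")
    loss_cfg = LossConfig(alpha=cfg.alpha)
    optimizer = SGD(model.parameters(), cfg.lr0, cfg.momentum,
                    cfg.weight_decay)
    start_epoch = 0
    if resume_state is not None:
        opt_state, start_epoch = resume_state
        if opt_state is not None:
            optimizer.load_state(opt_state)
    result = TrainResult()
    n = len(train_records)
    bs = min(cfg.batch_size, n)
    steps = max(n // bs, 1)
    model.train()
    for epoch in range(start_epoch, cfg.epochs):
        # per-epoch stream so a resumed run replays the same shuffles
        rng = np.random.default_rng([cfg.seed, epoch])
        order = rng.permutation(n)
        use_mosaic = cfg.mosaic and epoch < cfg.epochs - cfg.close_mosaic_epochs
        sums = np.zeros(4)
        for step in range(steps):
            optimizer.lr = _lr_at(cfg, epoch, step, steps)
            chunk = [train_records[i] for i in order[step * bs:(step + 1) * bs]]
            if use_mosaic:
                chunk = [_mosaic(train_records, rng) if rng.uniform() < 0.5
                         else rec for rec in chunk]
            images, gts = _to_batch(chunk)
            outputs = model(Tensor(images))
            total, box, cls, dfl = detection_loss(
                outputs, gts, loss_cfg, model.head.cfg.strides)
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            sums += (float(total.data), box, cls, dfl)
        row = {"epoch": epoch + 1, "lr": round(optimizer.lr, 6),
               "total": round(sums[0] / steps, 5),
               "box": round(sums[1] / steps, 5),
               "cls": round(sums[2] / steps, 5),
               "dfl": round(sums[3] / steps, 5)}
        if (val_records and eval_every
                and ((epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1)):
            from .evaluate import evaluate_model
            report = evaluate_model(model, val_records)
            row["val_map50"] = round(report.map50, 4)
            model.train()
        result.history.append(row)
    model.eval()
    if log_path is not None:
        Path(log_path).write_text(result.history_csv())
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, optimizer, cfg.epochs)
        result.checkpoint = str(checkpoint_path)
    return result
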
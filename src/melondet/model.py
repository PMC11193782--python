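"""Assembly of the full detectors.

Two variants share one topology (stem, four downsampling stages with
cross-stage-partial blocks, SPPF, a top-down/bottom-up feature-pyramid
neck, three-scale head at strides 8/16/32):

* ``v8n_baseline`` — the standard small-scale reference detector: plain
  bottlenecks in every C2f and the decoupled two-branch head.
* ``cml`` — the lightweight variant: backbone C2f inner blocks replaced
  by Faster-EMA (partial-convolution inverted residual + efficient
  multi-scale attention), neck C2f inner blocks replaced by plain
  FasterBlocks, and the shared-stem efficient head.

Channel widths and repeat counts follow the published n-scale rules:
nominal channels 64-128-256-512-1024 and repeats 3-6-6-3, scaled by
width 0.25 and depth 0.33 (hence 16-32-64-128-256 and 1-2-2-1).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import nn
from .autograd import Tensor, concatenate, no_grad
from .blocks import C2f, ConvBNSiLU, SPPF, BlockConfig
from .head import (BaselineDetect, DetectConfig, Detection, EfficientDetect,
                   decode_predictions, nms)

VARIANTS = ("v8n_baseline", "cml")


@dataclass
class ModelSpec:
    variant: str = "cml"
    nc: int = 3
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    max_channels: int = 1024
    input_size: int = 640
    reg_max: int = 16
    partial_ratio: float = 0.25
    expansion: int = 2
    ema_groups: int = 8
    conf_threshold: float = 0.25
    nms_iou_threshold: float = 0.65
    seed: int | None = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def scaled_channels(self, c: int) -> int:
        c = min(c, self.max_channels) * self.width_multiple
        return max(int(np.ceil(c / 8) * 8), 8)

    def scaled_depth(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls(**yaml.safe_load(text))


class DetectionModel(nn.Module):
    """Backbone + neck + head; forward returns per-level head outputs."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.scaled_channels
        c1, c2, c3, c4, c5 = (ch(64), ch(128), ch(256), ch(512), ch(1024))
        n3, n6 = spec.scaled_depth(3), spec.scaled_depth(6)
        if spec.variant == "cml":
            bb_kind, neck_kind = "faster_ema", "faster"
        else:
            bb_kind = neck_kind = "standard"

        def c2f(cin, cout, n, shortcut, kind):
            cfg = BlockConfig(cout // 2, cout // 2,
                              partial_ratio=spec.partial_ratio,
                              expansion=spec.expansion,
                              ema_groups=spec.ema_groups)
            return C2f(cin, cout, n, shortcut, kind, cfg, rng=rng)

        # backbone
        self.stem = ConvBNSiLU(3, c1, 3, 2, rng=rng)
        self.down1 = ConvBNSiLU(c1, c2, 3, 2, rng=rng)
        self.stage1 = c2f(c2, c2, n3, True, bb_kind)
        self.down2 = ConvBNSiLU(c2, c3, 3, 2, rng=rng)
        self.stage2 = c2f(c3, c3, n6, True, bb_kind)
        self.down3 = ConvBNSiLU(c3, c4, 3, 2, rng=rng)
        self.stage3 = c2f(c4, c4, n6, True, bb_kind)
        self.down4 = ConvBNSiLU(c4, c5, 3, 2, rng=rng)
        self.stage4 = c2f(c5, c5, n3, True, bb_kind)
        self.sppf = SPPF(c5, c5, 5, rng=rng)
        # neck (top-down then bottom-up)
        self.up = nn.Upsample(2)
        self.neck_p4 = c2f(c5 + c4, c4, n3, False, neck_kind)
        self.neck_p3 = c2f(c4 + c3, c3, n3, False, neck_kind)
        self.down_p3 = ConvBNSiLU(c3, c3, 3, 2, rng=rng)
        self.neck_n4 = c2f(c3 + c4, c4, n3, False, neck_kind)
        self.down_p4 = ConvBNSiLU(c4, c4, 3, 2, rng=rng)
        self.neck_n5 = c2f(c4 + c5, c5, n3, False, neck_kind)
        # head
        head_cfg = DetectConfig(nc=spec.nc, level_channels=(c3, c4, c5),
                                reg_max=spec.reg_max,
                                conf_threshold=spec.conf_threshold,
                                nms_iou_threshold=spec.nms_iou_threshold)
        if spec.variant == "cml":
            self.head = EfficientDetect(head_cfg, rng=rng)
        else:
            self.head = BaselineDetect(head_cfg, rng=rng)

    # -- forward ---------------------------------------------------------
    def features(self, x: Tensor) -> list[Tensor]:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input size must be divisible by 32")
        x = self.stem(x)
        x = self.stage1(self.down1(x))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))
        t4 = self.neck_p4(concatenate([self.up(p5), p4], axis=1))
        t3 = self.neck_p3(concatenate([self.up(t4), p3], axis=1))
        n4 = self.neck_n4(concatenate([self.down_p3(t3), t4], axis=1))
        n5 = self.neck_n5(concatenate([self.down_p4(n4), p5], axis=1))
        return [t3, n4, n5]

    def forward(self, x: Tensor) -> list[tuple[Tensor, Tensor]]:
        return self.head(self.features(x))

    def predict(self, images: np.ndarray,
                conf_threshold: float | None = None) -> list[list[Detection]]:
        """Run inference on a (B, 3, H, W) float batch and apply NMS."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                outputs = self.forward(Tensor(images))
                cfg = self.head.cfg
                if conf_threshold is not None:
                    from dataclasses import replace
                    cfg = replace(cfg, conf_threshold=conf_threshold)
                raw = decode_predictions(outputs, cfg)
                return [nms(dets, cfg.nms_iou_threshold) for dets in raw]
        finally:
            if was_training:
                self.train()

    def summary(self) -> str:
        rows = [f"{'module':<24}{'params':>12}"]
        total = 0
        for name, child in self._children.items():
            p = sum(int(np.prod(q.shape)) for q in child.parameters())
            total += p
            rows.append(f"{name:<24}{p:>12,}")
        rows.append(f"{'total':<24}{total:>12,}")
        return "\n".join(rows)


def build_model(spec: ModelSpec | None = None, **overrides) -> DetectionModel:
    """Build a detector; ``build_model(variant='cml', nc=3)`` also works."""
    if spec is None:
        spec = ModelSpec(**overrides)
    elif overrides:
        spec = ModelSpec(**{**asdict(spec), **overrides})
    return DetectionModel(spec)


def model_forward(model: DetectionModel, images: np.ndarray
                  ) -> list[tuple[Tensor, Tensor]]:
    """Deterministic forward pass on a normalised RGB batch."""
    return model(Tensor(images))
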
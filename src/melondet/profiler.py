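"""Exact parameter and FLOP accounting, plus the convolution-block bench.

Conventions (documented in docs/methods.md):

* Parameters are counted from the actual arrays: a convolution holds
  ``c_in/groups * c_out * k^2`` weights (+ ``c_out`` bias), a
  normalisation layer ``2c`` affine terms.  Only trainable parameters are
  counted by default.
* FLOPs are reported as ``2 x`` multiply-accumulates of the convolution
  (and matrix-product) layers, measured by one recorded forward pass at
  the stated input size.  Whole models are profiled *fused* (normalisation
  folded away, contributing nothing); isolated sub-modules may be profiled
  *unfused*, where a normalisation layer contributes 2 ops per element
  before the doubling.  Pooling, activations and attention matrix products
  are not counted (they are orders of magnitude below the convolutions).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, no_grad
from .blocks import ConvBNSiLU, PConv


# ---------------------------------------------------------------------------
# counting primitives
# ---------------------------------------------------------------------------

def count_params(module: nn.Module, trainable_only: bool = True) -> int:
    """Total element count of the module's (trainable) parameter arrays."""
    total = sum(int(np.prod(p.shape)) for p in module.parameters()
                if p.requires_grad or not trainable_only)
    return total


def recorded_macs(module: nn.Module, include_normalization: bool = False) -> int:
    """Multiply-accumulate count from the layers' last recorded forward.

    Counts include the convolution's batch dimension, so profiling is done
    on batch-1 inputs; blocks that fold channel groups into the batch axis
    (the attention module) are thereby charged for every group.
    """
    macs = 0
    for m in module.modules():
        if isinstance(m, nn.Conv2d):
            if m._last_out_hw is None:
                raise RuntimeError("run a forward pass before counting FLOPs")
            ho, wo = m._last_out_hw
            macs += (m.in_channels // m.groups) * m.kernel_size ** 2 \
                * m.out_channels * ho * wo * m._last_batch
        elif isinstance(m, nn.BatchNorm2d) and include_normalization:
            if m._last_numel is None:
                raise RuntimeError("run a forward pass before counting FLOPs")
            macs += 2 * m._last_numel
    return macs


def count_flops(module: nn.Module, run, include_normalization: bool = False
                ) -> int:
    """FLOPs (2 x MACs) of one forward executed by ``run()``."""
    with no_grad():
        module.eval()
        run()
    return 2 * recorded_macs(module, include_normalization)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ProfileRow:
    name: str
    params: int
    flops: int
    param_share: float
    flop_share: float


@dataclass
class ProfileReport:
    total_params: int
    total_flops: int
    input_size: int
    rows: list[ProfileRow] = field(default_factory=list)

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def table(self) -> str:
        lines = [f"{'module':<14}{'params':>12}{'GFLOPs':>10}{'param %':>9}"
                 f"{'flop %':>8}"]
        for r in self.rows:
            lines.append(f"{r.name:<14}{r.params:>12,}{r.flops / 1e9:>10.3f}"
                         f"{r.param_share:>8.1f}%{r.flop_share:>7.1f}%")
        lines.append(f"{'total':<14}{self.total_params:>12,}"
                     f"{self.gflops:>10.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "total_params": self.total_params,
            "total_flops": self.total_flops,
            "params_m": round(self.params_m, 4),
            "gflops": round(self.gflops, 4),
            "input_size": self.input_size,
            "modules": [
                {"name": r.name, "params": r.params, "flops": r.flops,
                 "param_share": round(r.param_share, 2),
                 "flop_share": round(r.flop_share, 2)} for r in self.rows],
        }


def profile_model(model, imgsz: int = 640) -> ProfileReport:
    """Profile a full detector (fused convention) at ``imgsz`` input.

    The per-module breakdown covers the model's top-level children and
    sums exactly to the totals.
    """
    x = np.zeros((1, 3, imgsz, imgsz), dtype=np.float32)
    with no_grad():
        model.eval()
        model(Tensor(x))
    total_p = count_params(model)
    total_f = 2 * recorded_macs(model)
    rows = []
    for name, child in model._children.items():
        p = count_params(child)
        f = 2 * recorded_macs(child)
        rows.append(ProfileRow(name, p, f,
                               100.0 * p / max(total_p, 1),
                               100.0 * f / max(total_f, 1)))
    report = ProfileReport(total_p, total_f, imgsz, rows)
    assert sum(r.params for r in report.rows) == total_p
    assert sum(r.flops for r in report.rows) == total_f
    return report


def profile_head(head, imgsz: int = 640, include_normalization: bool = True
                 ) -> ProfileReport:
    """Profile a detection head alone over its three pyramid levels.

    Feature maps are sized ``imgsz/8, imgsz/16, imgsz/32`` with the head's
    configured level channels.  Heads are isolated sub-modules, profiled
    unfused (normalisation counted at 2 ops/element).
    """
    cfg = head.cfg
    feats = [Tensor(np.zeros((1, c, imgsz // s, imgsz // s), np.float32))
             for c, s in zip(cfg.level_channels, cfg.strides)]
    flops = count_flops(head, lambda: head(feats),
                        include_normalization=include_normalization)
    return ProfileReport(count_params(head), flops, imgsz)


# ---------------------------------------------------------------------------
# convolution-block benchmark zoo
# ---------------------------------------------------------------------------

class _ConvBlock(nn.Module):
    """3x3 convolution with bias followed by batch normalisation."""

    def __init__(self, c: int = 128, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c, c, 3, bias=True, rng=rng)
        self.bn = nn.BatchNorm2d(c)

    def forward(self, x):
        return self.bn(self.conv(x))


class _DWConvBlock(nn.Module):
    """Depthwise-separable block: 3x3 depthwise + 1x1 pointwise, each with
    bias and batch normalisation."""

    def __init__(self, c: int = 128, rng=None):
        super().__init__()
        self.dw = nn.Conv2d(c, c, 3, groups=c, bias=True, rng=rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.pw = nn.Conv2d(c, c, 1, bias=True, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)

    def forward(self, x):
        return self.bn2(self.pw(self.bn1(self.dw(x))))


class _GSConvBlock(nn.Module):
    """Slim conv: 3x3 conv to half width, 5x5 depthwise on that half,
    concatenation and channel shuffle."""

    def __init__(self, c: int = 128, rng=None):
        super().__init__()
        half = c // 2
        self.conv = nn.Conv2d(c, half, 3, bias=True, rng=rng)
        self.bn1 = nn.BatchNorm2d(half)
        self.dw = nn.Conv2d(half, half, 5, groups=half, bias=True, rng=rng)
        self.bn2 = nn.BatchNorm2d(half)
        self.half = half

    def forward(self, x):
        a = self.bn1(self.conv(x))
        b = self.bn2(self.dw(a))
        y = nn.concatenate([a, b], axis=1)
        B, C, H, W = y.shape
        return y.reshape(B, 2, C // 2, H, W).transpose(0, 2, 1, 3, 4) \
                .reshape(B, C, H, W)


class _DSConvBlock(nn.Module):
    """Distribution-shift style block: a fixed quantised 3x3 kernel
    (non-trainable buffer) with a trainable batch normalisation on top —
    the only trainable parameters are the 2c affine terms."""

    def __init__(self, c: int = 128, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kernel = rng.integers(-1, 2, size=(c, c, 3, 3)).astype(np.float32)
        kernel *= 1.0 / np.sqrt(9 * c)
        self.register_buffer("kernel", kernel)
        self.bn = nn.BatchNorm2d(c)

    def forward(self, x):
        return self.bn(nn.conv2d(x, Tensor(self.kernel), None, 1, 1))


class _PConvBlock(nn.Module):
    """Partial 3x3 convolution on a quarter of the channels (no bias),
    with batch normalisation over the full channel count."""

    def __init__(self, c: int = 128, rng=None):
        super().__init__()
        self.pconv = PConv(c, 0.25, 3, rng=rng)
        self.bn = nn.BatchNorm2d(c)

    def forward(self, x):
        return self.bn(self.pconv(x))


class _PConvConvBlock(nn.Module):
    """The head-stem combination: partial 3x3 conv then a 1x1 conv."""

    def __init__(self, c: int = 128, rng=None):
        super().__init__()
        self.pconv = PConv(c, 0.25, 3, rng=rng)
        self.conv = ConvBNSiLU(c, c, 1, rng=rng)

    def forward(self, x):
        return self.conv(self.pconv(x))


BLOCK_ZOO: dict[str, type] = {
    "conv": _ConvBlock,
    "dwconv": _DWConvBlock,
    "gsconv": _GSConvBlock,
    "dsconv": _DSConvBlock,
    "pconv": _PConvBlock,
    "pconv+conv": _PConvConvBlock,
}


@dataclass
class BenchProtocol:
    block: str = "pconv"
    channels: int = 128
    spatial: int = 56
    batch: int = 1
    warmup_iters: int = 1000
    timed_iters: int = 3000
    seed: int = 0


@dataclass
class BenchReport:
    block: str
    mean_time_ms: float
    fps: float
    params: int
    flops: int
    timed_iters: int


def make_block(name: str, channels: int = 128, rng=None) -> nn.Module:
    try:
        cls = BLOCK_ZOO[name]
    except KeyError:
        raise KeyError(f"unknown block {name!r}; registry: "
                       f"{sorted(BLOCK_ZOO)}") from None
    return cls(channels, rng=rng)


def benchmark_block(protocol: BenchProtocol) -> BenchReport:
    """Time a zoo block (timing is hardware-bound and purely informative;
    the parameter and FLOP columns are deterministic)."""
    rng = np.random.default_rng(protocol.seed)
    block = make_block(protocol.block, protocol.channels, rng=rng)
    block.eval()
    x = Tensor(rng.normal(size=(protocol.batch, protocol.channels,
                                protocol.spatial, protocol.spatial))
               .astype(np.float32))
    with no_grad():
        for _ in range(protocol.warmup_iters):
            block(x)
        start = time.perf_counter()
        for _ in range(protocol.timed_iters):
            block(x)
        elapsed = time.perf_counter() - start
    flops = 2 * recorded_macs(block, include_normalization=True)
    mean_ms = elapsed / protocol.timed_iters * 1e3
    return BenchReport(protocol.block, mean_ms, 1e3 / mean_ms,
                       count_params(block), flops, protocol.timed_iters)
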
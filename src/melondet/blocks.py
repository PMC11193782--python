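"""Building blocks of the lightweight detector.

The two bespoke blocks are:

* :class:`FasterBlock` — an inverted-residual block built around a
  *partial convolution* (:class:`PConv`): a 3x3 convolution applied to the
  first ``c_p = round(r * c)`` channels only (``r = 1/4`` by default),
  the remaining channels passing through untouched, followed by a 1x1
  expansion (batch norm + ReLU) and a 1x1 reduction.  Only the expansion
  layer carries normalisation and activation.
* :class:`FasterEMA` — the same inverted residual with an Efficient
  Multi-Scale Attention (:class:`EMA`) module appended before the
  residual addition.  EMA splits channels into groups and modulates each
  group by attention maps built from directionally pooled context (1x1
  path) and local 3x3 context, combined by cross-spatial softmax
  aggregation.

Both slot into the standard cross-stage-partial :class:`C2f` container as
drop-in replacements for its plain :class:`Bottleneck`.

FLOP closed forms: a k x k convolution with equal input/output channel
count ``c`` on an ``h x w`` map costs ``h*w*k^2*c^2`` multiply-accumulates;
the partial convolution costs ``h*w*k^2*c_p^2``, i.e. an ``r^2`` fraction
(1/16 at ``r = 1/4``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, concatenate


# ---------------------------------------------------------------------------
# closed-form FLOP counts
# ---------------------------------------------------------------------------

def conv_flops(h: int, w: int, k: int, c: int) -> int:
    """Multiply-accumulate count of a k x k conv with c input = output channels."""
    if min(h, w, k, c) < 1:
        raise ValueError("all arguments must be >= 1")
    return h * w * k * k * c * c


def pconv_flops(h: int, w: int, k: int, c_p: int) -> int:
    """Multiply-accumulate count of a partial conv touching c_p channels."""
    if min(h, w, k, c_p) < 1:
        raise ValueError("all arguments must be >= 1")
    return h * w * k * k * c_p * c_p


@dataclass
class BlockConfig:
    """Shared configuration for the bespoke blocks.

    partial_ratio is the fraction r of channels the partial convolution
    touches; expansion is the hidden-width multiplier of the inverted
    residual; ema_groups is the number of channel groups the attention
    module splits a feature map into.
    """

    c_in: int
    c_out: int
    partial_ratio: float = 0.25
    kernel: int = 3
    expansion: int = 2
    shortcut: bool = True
    ema_groups: int = 8

    def __post_init__(self):
        if not (0 < self.partial_ratio <= 1):
            raise ValueError("partial_ratio must lie in (0, 1]")
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")
        if round(self.c_in * self.partial_ratio) < 1:
            raise ValueError("partial_ratio leaves no channels for the conv")


def global_avg_pool(x: Tensor) -> Tensor:
    """Channel-wise spatial mean z_c = (1/HW) sum_ij x_c(i, j)."""
    return nn.adaptive_avg_pool(x, (1, 1))


def pool_height(x: Tensor) -> Tensor:
    """Directional pooling that averages the width axis away (keeps H)."""
    return nn.adaptive_avg_pool(x, (None, 1))


def pool_width(x: Tensor) -> Tensor:
    """Directional pooling that averages the height axis away (keeps W)."""
    return nn.adaptive_avg_pool(x, (1, None))


# ---------------------------------------------------------------------------
# standard convolution wrapper (conv + BN + SiLU), as in the base detector
# ---------------------------------------------------------------------------

class ConvBNSiLU(nn.Module):
    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 rng: np.random.Generator | None = None, act: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, stride=s, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    """Plain residual bottleneck: two 3x3 convs at full width (e = 1)."""

    def __init__(self, c: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cv1 = ConvBNSiLU(c, c, 3, rng=rng)
        self.cv2 = ConvBNSiLU(c, c, 3, rng=rng)
        self.add = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class PConv(nn.Module):
    """Partial convolution: k x k conv on the first c_p channels, identity
    on the rest.  The touched slice is the *first* contiguous block of
    channels, matching the reference implementation's slicing mode."""

    def __init__(self, c: int, ratio: float = 0.25, k: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c = c
        self.c_p = max(1, round(c * ratio))
        if self.c_p > c:
            raise ValueError("c_p exceeds channel count")
        self.conv = nn.Conv2d(self.c_p, self.c_p, k, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        active = self.conv(x[:, :self.c_p])
        if self.c_p == self.c:
            return active
        return concatenate([active, x[:, self.c_p:]], axis=1)


class FasterBlock(nn.Module):
    """Inverted residual around a partial convolution.

    PConv(k=3, r) -> 1x1 conv expanding c -> e*c (BN + ReLU) -> 1x1 conv
    reducing back to c (no norm, no activation), plus identity shortcut.
    """

    def __init__(self, c: int, ratio: float = 0.25, expansion: int = 2,
                 shortcut: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.pconv = PConv(c, ratio, 3, rng=rng)
        self.expand = nn.Conv2d(c, expansion * c, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(expansion * c)
        self.act = nn.ReLU()
        self.reduce = nn.Conv2d(expansion * c, c, 1, bias=False, rng=rng)
        self.add = shortcut

    def _inner(self, x: Tensor) -> Tensor:
        return self.reduce(self.act(self.bn(self.expand(self.pconv(x)))))

    def forward(self, x: Tensor) -> Tensor:
        y = self._inner(x)
        return x + y if self.add else y


class EMA(nn.Module):
    """Efficient Multi-Scale Attention over channel groups.

    Channels are reshaped into ``groups`` sub-maps.  A 1x1 path encodes
    H- and W-direction pooled context through a shared 1x1 conv with
    sigmoid gating (followed by group normalisation); a 3x3 path captures
    local context.  Per-group attention maps are formed by multiplying
    softmax-normalised globally pooled descriptors of each path with the
    flattened features of the other, summing, and sigmoid-gating the
    input groups.  Output shape equals input shape.
    """

    def __init__(self, channels: int, groups: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % groups:
            raise ValueError("channels must be divisible by ema groups")
        self.channels = channels
        self.groups = groups
        cg = channels // groups
        self.conv1x1 = nn.Conv2d(cg, cg, 1, bias=True, rng=rng)
        self.conv3x3 = nn.Conv2d(cg, cg, 3, bias=True, rng=rng)
        self.gn = nn.GroupNorm(cg, cg)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        g, cg = self.groups, c // self.groups
        gx = x.reshape(b * g, cg, h, w)
        # 1x1 path: directional pooling -> shared conv -> sigmoid gates
        x_h = pool_height(gx)                                # (bg, cg, h, 1)
        x_w = pool_width(gx).transpose(0, 1, 3, 2)           # (bg, cg, w, 1)
        hw = self.conv1x1(concatenate([x_h, x_w], axis=2))   # (bg, cg, h+w, 1)
        gate_h = hw[:, :, :h].sigmoid()
        gate_w = hw[:, :, h:].transpose(0, 1, 3, 2).sigmoid()
        x1 = self.gn(gx * gate_h * gate_w)
        # 3x3 path
        x2 = self.conv3x3(gx)
        # cross-spatial aggregation
        d1 = global_avg_pool(x1).reshape(b * g, cg, 1).transpose(0, 2, 1)
        d2 = global_avg_pool(x2).reshape(b * g, cg, 1).transpose(0, 2, 1)
        a1 = d1.softmax(axis=2) @ x2.reshape(b * g, cg, h * w)
        a2 = d2.softmax(axis=2) @ x1.reshape(b * g, cg, h * w)
        weights = (a1 + a2).reshape(b * g, 1, h, w).sigmoid()
        return (gx * weights).reshape(b, c, h, w)


class FasterEMA(nn.Module):
    """FasterBlock body with EMA appended: x + EMA(reduce(expand(PConv(x))))."""

    def __init__(self, c: int, ratio: float = 0.25, expansion: int = 2,
                 shortcut: bool = True, ema_groups: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.body = FasterBlock(c, ratio, expansion, shortcut=False, rng=rng)
        self.ema = EMA(c, ema_groups, rng=rng)
        self.add = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.ema(self.body._inner(x))
        return x + y if self.add else y


_INNER_BLOCKS = {
    "standard": lambda c, shortcut, rng, cfg: Bottleneck(c, shortcut, rng=rng),
    "faster": lambda c, shortcut, rng, cfg: FasterBlock(
        c, cfg.partial_ratio, cfg.expansion, shortcut, rng=rng),
    "faster_ema": lambda c, shortcut, rng, cfg: FasterEMA(
        c, cfg.partial_ratio, cfg.expansion, shortcut, cfg.ema_groups, rng=rng),
}


class C2f(nn.Module):
    """Cross-stage-partial container: 1x1 conv to hidden width, split into
    two halves, a chain of inner blocks each appending its output, then a
    1x1 fusion conv over the concatenation."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False,
                 block_kind: str = "standard",
                 cfg: BlockConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n < 1:
            raise ValueError("n_blocks must be >= 1")
        if block_kind not in _INNER_BLOCKS:
            raise ValueError(f"unknown block kind {block_kind!r}; "
                             f"choose from {sorted(_INNER_BLOCKS)}")
        self.c_hidden = c2 // 2
        cfg = cfg or BlockConfig(self.c_hidden, self.c_hidden)
        self.cv1 = ConvBNSiLU(c1, 2 * self.c_hidden, 1, rng=rng)
        self.cv2 = ConvBNSiLU((2 + n) * self.c_hidden, c2, 1, rng=rng)
        self.m = nn.ModuleList([
            _INNER_BLOCKS[block_kind](self.c_hidden, shortcut, rng, cfg)
            for _ in range(n)])

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        ys = [y[:, :self.c_hidden], y[:, self.c_hidden:]]
        for block in self.m:
            ys.append(block(ys[-1]))
        return self.cv2(concatenate(ys, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained k=5 max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        ch = c1 // 2
        self.cv1 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv2 = ConvBNSiLU(ch * 4, c2, 1, rng=rng)
        self.pool = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x: Tensor) -> Tensor:
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concatenate([y0, y1, y2, y3], axis=1))


# functional wrappers mirroring the operation-level API -----------------------

def pconv_forward(x: Tensor, cfg: BlockConfig,
                  rng: np.random.Generator | None = None) -> Tensor:
    if cfg.c_in != cfg.c_out:
        raise ValueError("partial convolution requires c_in == c_out")
    return PConv(cfg.c_in, cfg.partial_ratio, cfg.kernel, rng=rng)(x)


def faster_block_forward(x: Tensor, cfg: BlockConfig,
                         rng: np.random.Generator | None = None) -> Tensor:
    if cfg.c_in != cfg.c_out:
        raise ValueError("faster block requires c_in == c_out")
    return FasterBlock(cfg.c_in, cfg.partial_ratio, cfg.expansion,
                       cfg.shortcut, rng=rng)(x)


def ema_forward(x: Tensor, groups: int,
                rng: np.random.Generator | None = None) -> Tensor:
    return EMA(x.shape[1], groups, rng=rng)(x)


def faster_ema_forward(x: Tensor, cfg: BlockConfig,
                       rng: np.random.Generator | None = None) -> Tensor:
    if cfg.c_in != cfg.c_out:
        raise ValueError("faster-ema block requires c_in == c_out")
    return FasterEMA(cfg.c_in, cfg.partial_ratio, cfg.expansion,
                     cfg.shortcut, cfg.ema_groups, rng=rng)(x)


def c2f_forward(x: Tensor, c_out: int, n_blocks: int,
                block_kind: str = "standard",
                rng: np.random.Generator | None = None) -> Tensor:
    return C2f(x.shape[1], c_out, n_blocks, shortcut=True,
               block_kind=block_kind, rng=rng)(x)
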
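"""Neural-network layers on top of :mod:`melondet.autograd`.

Only the layer types the detector actually uses are implemented:
2-D convolution (with grouped/depthwise support), batch and group
normalisation, max pooling, nearest-neighbour upsampling and the usual
activations.  Every layer is a :class:`Module`; modules compose through
attribute assignment exactly as in the mainstream frameworks, and expose
``parameters()`` / ``state_dict()`` for the optimiser and checkpoints.

Convolutions additionally record the spatial size of their most recent
output (``_last_out_hw``) so the profiler can turn one forward pass into
an exact multiply-accumulate count.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, concatenate, is_grad_enabled


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks child modules, parameters and buffers."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- traversal -------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._children.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def modules(self) -> Iterator["Module"]:
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules(prefix):
            for p_name, p in mod._params.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for mod_name, mod in self.named_modules(prefix):
            for b_name in mod._buffers:
                arr = getattr(mod, b_name)
                yield (f"{mod_name}.{b_name}" if mod_name else b_name), arr

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialisation ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[f"{name}"] = np.array(b, copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (mod, b_name)
                   for mod_name, mod in self.named_modules()
                   for b_name in mod._buffers
                   for name in [f"{mod_name}.{b_name}" if mod_name else b_name]}
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = value.astype(np.float32).copy()
            elif name in buffers:
                mod, b_name = buffers[name]
                mod.register_buffer(b_name, np.array(value, copy=True))
            else:
                raise KeyError(f"unexpected key {name!r} in state dict")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._children[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = list(modules)
        for i, m in enumerate(self._list):
            self._children[str(i)] = m

    def append(self, m: Module) -> None:
        self._children[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


# ---------------------------------------------------------------------------
# functional convolution
# ---------------------------------------------------------------------------

def _conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
                    groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Returns (output, strided windows view of the padded input)."""
    kh, kw = w.shape[2], w.shape[3]
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    if stride > 1:
        win = win[:, :, ::stride, ::stride]
    cin, cout = x.shape[1], w.shape[0]
    if groups == 1:
        out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    elif groups == cin and cout == cin:  # depthwise
        out = np.einsum("bchwkl,ckl->bchw", win, w[:, 0], optimize=True)
    else:
        cg_in, cg_out = cin // groups, cout // groups
        parts = []
        for g in range(groups):
            wg = w[g * cg_out:(g + 1) * cg_out]
            xg = win[:, g * cg_in:(g + 1) * cg_in]
            og = np.tensordot(xg, wg, axes=([1, 4, 5], [1, 2, 3]))
            parts.append(og.transpose(0, 3, 1, 2))
        out = np.concatenate(parts, axis=1)
    return out.astype(np.float32, copy=False), win


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    out_data, win = _conv2d_forward(x.data, w.data, stride, padding, groups)
    B, cin, H, W = x.shape
    cout, _, kh, kw = w.shape
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def backward(g):
        go = np.ascontiguousarray(g)  # (B, cout, Ho, Wo)
        depthwise = groups == cin and cout == cin
        if w.requires_grad:
            if groups == 1:
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        gw[:, :, i, j] = np.tensordot(
                            go, win[..., i, j], axes=([0, 2, 3], [0, 2, 3]))
            elif depthwise:
                gw = np.einsum("bchw,bchwkl->ckl", go, win,
                               optimize=True)[:, None]
            else:
                cg_in, cg_out = cin // groups, cout // groups
                gw = np.empty_like(w.data)
                for gi in range(groups):
                    sl_o = slice(gi * cg_out, (gi + 1) * cg_out)
                    sl_i = slice(gi * cg_in, (gi + 1) * cg_in)
                    for i in range(kh):
                        for j in range(kw):
                            gw[sl_o, :, i, j] = np.tensordot(
                                go[:, sl_o], win[:, sl_i, :, :, i, j],
                                axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if x.requires_grad:
            Hp, Wp = H + 2 * padding, W + 2 * padding
            gxp = np.zeros((B, cin, Hp, Wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    if groups == 1:
                        c = np.tensordot(go, w.data[:, :, i, j],
                                         axes=([1], [0]))  # (B,Ho,Wo,cin)
                        c = c.transpose(0, 3, 1, 2)
                    elif depthwise:
                        c = go * w.data[:, 0, i, j][None, :, None, None]
                    else:
                        cg_in, cg_out = cin // groups, cout // groups
                        c = np.empty((B, cin, Ho, Wo), dtype=np.float32)
                        for gi in range(groups):
                            cc = np.tensordot(
                                go[:, gi * cg_out:(gi + 1) * cg_out],
                                w.data[gi * cg_out:(gi + 1) * cg_out, :, i, j],
                                axes=([1], [0]))
                            c[:, gi * cg_in:(gi + 1) * cg_in] = \
                                cc.transpose(0, 3, 1, 2)
                    gxp[:, :, i:i + Ho * stride:stride,
                        j:j + Wo * stride:stride] += c
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)
        if b is not None and b.requires_grad:
            b._accumulate(go.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, backward)
    if b is not None:
        # fold bias into the forward result (gradient handled above)
        out.data = out.data + b.data[None, :, None, None]
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(
            -bound, bound, (out_channels, in_channels // groups,
                            kernel_size, kernel_size)).astype(np.float32))
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels)
                              .astype(np.float32)) if bias else None
        self._last_out_hw: tuple[int, int] | None = None
        self._last_batch: int = 1

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, self.stride, self.padding,
                     self.groups)
        self._last_out_hw = (out.shape[2], out.shape[3])
        self._last_batch = out.shape[0]
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))
        self._last_numel: int | None = None

    def forward(self, x: Tensor) -> Tensor:
        self._last_numel = x.size
        shape = (1, self.num_features, 1, 1)
        if self.training and is_grad_enabled():
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size / self.num_features
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.reshape(-1))
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
            inv = (var + self.eps) ** -0.5
            return (centered * inv * self.weight.reshape(shape)
                    + self.bias.reshape(shape))
        scale = self.weight.data / np.sqrt(self.running_var + self.eps)
        shift = self.bias.data - self.running_mean * scale
        return x * Tensor(scale.reshape(shape)) + Tensor(shift.reshape(shape))


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must be divisible by groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.num_groups
        xg = x.reshape(B, g, C // g, H, W)
        mean = xg.mean(axis=(2, 3, 4), keepdims=True)
        centered = xg - mean
        var = (centered * centered).mean(axis=(2, 3, 4), keepdims=True)
        normed = (centered * (var + self.eps) ** -0.5).reshape(B, C, H, W)
        shape = (1, C, 1, 1)
        return normed * self.weight.reshape(shape) + self.bias.reshape(shape)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        if s > 1:
            win = win[:, :, ::s, ::s]
        out_data = win.max(axis=(4, 5))

        def backward(g):
            B, C, H, W = x.shape
            Hp, Wp = H + 2 * p, W + 2 * p
            Ho, Wo = out_data.shape[2], out_data.shape[3]
            mask = (win == out_data[..., None, None])
            mask = mask / np.maximum(mask.sum(axis=(4, 5), keepdims=True), 1)
            contrib = mask * g[..., None, None]
            gxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += contrib[..., i, j]
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            x._accumulate(gxp)

        return Tensor._make(out_data.astype(np.float32), (x,), backward)


class Upsample(Module):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        s = self.scale
        data = x.data.repeat(s, axis=2).repeat(s, axis=3)

        def backward(g):
            B, C, H, W = x.shape
            x._accumulate(g.reshape(B, C, H, s, W, s).sum(axis=(3, 5)))

        return Tensor._make(data, (x,), backward)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def adaptive_avg_pool(x: Tensor, output: tuple[int | None, int | None]) -> Tensor:
    """Average pooling to ``(1,1)``, ``(None,1)`` (per-row) or ``(1,None)``.

    Covers global average pooling and the two directional poolings used by
    the multi-scale attention block.
    """
    oh, ow = output
    if oh == 1 and ow == 1:
        return x.mean(axis=(2, 3), keepdims=True)
    if ow == 1:  # pool width away, keep height
        return x.mean(axis=3, keepdims=True)
    if oh == 1:  # pool height away, keep width
        return x.mean(axis=2, keepdims=True)
    raise ValueError("unsupported adaptive pooling target")


__all__ = [
    "Parameter", "Module", "Sequential", "ModuleList", "Conv2d", "BatchNorm2d",
    "GroupNorm", "MaxPool2d", "Upsample", "SiLU", "ReLU", "Sigmoid", "Identity",
    "conv2d", "adaptive_avg_pool", "concatenate",
]
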
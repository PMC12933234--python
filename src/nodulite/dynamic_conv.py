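"""Omni-dimensional dynamic convolution, the C3_ODC block, and GSConv.

ODConv holds N candidate kernels and, per input sample, predicts four
attention weight sets from a squeezed (globally averaged) feature vector:

* ``alpha_s`` — spatial, one weight per kernel tap (k x k),
* ``alpha_c`` — input channel,
* ``alpha_f`` — output channel (filter),
* ``alpha_w`` — kernel number (N).

The effective kernel is the attention-modulated sum
``sum_i alpha_w[i] * (alpha_f ⊗ alpha_c ⊗ alpha_s) ⊙ W_i`` and the layer
output is an ordinary convolution of the input with that per-sample kernel.
All four branches are sigmoid-normalized by default; a softmax option for
the kernel-number branch is provided for comparability with the original
dynamic-convolution formulation.

GSConv is the lightweight unit used in the fusion neck: a standard
convolution producing half the output channels, a depthwise convolution on
top of it, concatenation, and a fixed interleaving channel shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import ConvBNSiLU
from .boxes_and_losses import ConfigError
from .nn import Module, Tensor

__all__ = [
    "ODConvConfig", "ODConvAttention", "ODConv", "ODConvBNSiLU",
    "odconv_attention", "odconv_forward", "C3_ODC", "GSConv",
    "gs_shuffle_perm",
]


@dataclass(frozen=True)
class ODConvConfig:
    """Shape/capacity configuration of an ODConv layer.

    ``reduction_ratio`` sets the squeeze width ``max(in_channels // r,
    hidden_floor)`` of the shared attention trunk.
    """

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    n_kernels: int = 4
    reduction_ratio: int = 16
    hidden_floor: int = 16
    stride: int = 1
    padding: int | None = None  # None -> k // 2

    def __post_init__(self):
        if self.n_kernels < 1:
            raise ConfigError("n_kernels must be >= 1")
        if self.hidden_width < 4:
            raise ConfigError("attention hidden width must be >= 4")

    @property
    def hidden_width(self) -> int:
        return max(self.in_channels // self.reduction_ratio, self.hidden_floor)

    @property
    def pad(self) -> int:
        return self.kernel_size // 2 if self.padding is None else self.padding


@dataclass
class ODConvAttention:
    """The four per-sample attention weight sets (batch leading axis)."""

    alpha_s: Tensor  # (B, k, k)
    alpha_c: Tensor  # (B, Cin)
    alpha_f: Tensor  # (B, Cout)
    alpha_w: Tensor  # (B, N)


class ODConv(Module):
    """Omni-dimensional dynamic convolution layer (no bias, NCHW)."""

    def __init__(self, cfg: ODConvConfig, kernel_softmax: bool = False):
        super().__init__()
        self.cfg = cfg
        self.kernel_softmax = kernel_softmax
        k, n = cfg.kernel_size, cfg.n_kernels
        fan_in = cfg.in_channels * k * k
        self.weight = Tensor(
            nn._kaiming((n, cfg.out_channels, cfg.in_channels, k, k), fan_in, nn._INIT_RNG),
            requires_grad=True)
        h = cfg.hidden_width
        self.fc = nn.Linear(cfg.in_channels, h)
        self.head_s = nn.Linear(h, k * k)
        self.head_c = nn.Linear(h, cfg.in_channels)
        self.head_f = nn.Linear(h, cfg.out_channels)
        self.head_w = nn.Linear(h, n)

    def attention(self, x: Tensor) -> ODConvAttention:
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} channels, got {x.shape[1]}")
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ValueError("spatially empty input")
        pooled = x.mean(axis=(2, 3))                  # (B, Cin)
        hid = self.fc(pooled).relu()
        k = cfg.kernel_size
        a_s = self.head_s(hid).sigmoid().reshape(x.shape[0], k, k)
        a_c = self.head_c(hid).sigmoid()
        a_f = self.head_f(hid).sigmoid()
        zw = self.head_w(hid)
        if self.kernel_softmax:
            m = Tensor(zw.data.max(axis=1, keepdims=True))
            e = (zw - m).exp()
            a_w = e / e.sum(axis=1, keepdims=True)
        else:
            a_w = zw.sigmoid()
        return ODConvAttention(a_s, a_c, a_f, a_w)

    def forward(self, x: Tensor) -> Tensor:
        return odconv_forward(x, self.weight, self.attention(x), self.cfg)


def odconv_attention(x: Tensor, layer: ODConv) -> ODConvAttention:
    """Compute the four attention sets of ``layer`` for input batch ``x``."""
    return layer.attention(x)


def odconv_forward(x: Tensor, kernels: Tensor, att: ODConvAttention,
                   cfg: ODConvConfig) -> Tensor:
    """Convolve ``x`` with the attention-aggregated kernel, per sample.

    ``kernels`` has shape (N, Cout, Cin, k, k).  Because the spatial, input-
    and output-channel attentions are shared across the N kernels, the
    aggregation factorizes: first mix kernels with ``alpha_w``, then scale by
    the outer product of the other three sets.
    """
    n, cout, cin, k, _ = kernels.shape
    b = x.shape[0]
    if att.alpha_w.shape != (b, n) or att.alpha_c.shape != (b, cin) \
            or att.alpha_f.shape != (b, cout) or att.alpha_s.shape != (b, k, k):
        raise ValueError("attention/kernel shape mismatch")
    mixed = att.alpha_w.matmul(kernels.reshape(n, cout * cin * k * k))
    mixed = mixed.reshape(b, cout, cin, k, k)
    agg = mixed * att.alpha_f.reshape(b, cout, 1, 1, 1) \
        * att.alpha_c.reshape(b, 1, cin, 1, 1) \
        * att.alpha_s.reshape(b, 1, 1, k, k)
    outs = []
    for i in range(b):
        outs.append(nn.conv2d(x[i : i + 1], agg[i], None, cfg.stride, cfg.pad))
    return nn.concat(outs, axis=0) if len(outs) > 1 else outs[0]


class ODConvBNSiLU(Module):
    """ODConv -> batch norm -> SiLU, drop-in for :class:`ConvBNSiLU`."""

    def __init__(self, c1: int, c2: int, k: int = 3, s: int = 1,
                 n_kernels: int = 4, reduction_ratio: int = 16,
                 kernel_softmax: bool = False):
        super().__init__()
        self.od = ODConv(ODConvConfig(c1, c2, k, n_kernels, reduction_ratio, stride=s),
                         kernel_softmax=kernel_softmax)
        self.bn = nn.BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.od(x)).silu()


class _ODBottleneck(Module):
    """Residual bottleneck whose 3x3 convolution is an ODConv."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True,
                 n_kernels: int = 4, reduction_ratio: int = 16,
                 replace_1x1: bool = False, kernel_softmax: bool = False):
        super().__init__()
        if replace_1x1:
            self.cv1 = ODConvBNSiLU(c1, c2, 1, 1, n_kernels, reduction_ratio, kernel_softmax)
        else:
            self.cv1 = ConvBNSiLU(c1, c2, 1, 1)
        self.cv2 = ODConvBNSiLU(c2, c2, 3, 1, n_kernels, reduction_ratio, kernel_softmax)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3_ODC(Module):
    """C3 block with the bottleneck convolutions replaced by ODConv.

    Topology is identical to the standard C3 (split, n bottlenecks, concat,
    1x1 fuse); by default only each bottleneck's 3x3 convolution becomes an
    ODConv (``replace_1x1`` extends it to the 1x1 reduce convs).
    """

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 e: float = 0.5, n_kernels: int = 4, reduction_ratio: int = 16,
                 replace_1x1: bool = False, kernel_softmax: bool = False):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv2 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv3 = ConvBNSiLU(2 * c_, c2, 1, 1)
        self.m = [
            _ODBottleneck(c_, c_, shortcut, n_kernels, reduction_ratio,
                          replace_1x1, kernel_softmax)
            for _ in range(n)
        ]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(nn.concat([y, self.cv2(x)], axis=1))


def c3_odc_block(x: Tensor, block: C3_ODC) -> Tensor:
    """Apply a :class:`C3_ODC` block (functional convenience wrapper)."""
    return block(x)


# ---------------------------------------------------------------------------
# GSConv
# ---------------------------------------------------------------------------


def gs_shuffle_perm(c2: int) -> np.ndarray:
    """Channel permutation interleaving the standard- and depthwise halves."""
    half = c2 // 2
    perm = np.empty(c2, dtype=np.int64)
    perm[0::2] = np.arange(half)          # even slots <- standard-conv half
    perm[1::2] = np.arange(half, c2)      # odd slots  <- depthwise half
    return perm


class GSConv(Module):
    """Half standard + half depthwise convolution with channel shuffle.

    A standard (stride-carrying) convolution produces c2/2 channels, a
    stride-1 depthwise convolution refines them, the two halves are
    concatenated and interleaved.  Parameter cost is roughly half that of a
    dense c1 -> c2 convolution.
    """

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, dw_k: int = 5):
        super().__init__()
        if c2 % 2:
            raise ConfigError(f"GSConv output channels must be even, got {c2}")
        half = c2 // 2
        self.conv = ConvBNSiLU(c1, half, k, s)
        self.dw = ConvBNSiLU(half, half, dw_k, 1, g=half)
        self.perm = gs_shuffle_perm(c2)

    def forward(self, x: Tensor) -> Tensor:
        a = self.conv(x)
        b = self.dw(a)
        y = nn.concat([a, b], axis=1)
        return y[:, self.perm]


def gsconv(x: Tensor, layer: GSConv) -> Tensor:
    """Apply a :class:`GSConv` layer (functional convenience wrapper)."""
    return layer(x)
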
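"""Shared detector building blocks (CSP-style, SiLU-activated).

These are the standard blocks of the YOLOv5-family architecture: a
conv + batch-norm + SiLU unit, the residual bottleneck, the C3
cross-stage-partial block, and the fast spatial-pyramid-pooling tail.
The attention / lightweight variants live in :mod:`nodulite.dynamic_conv`.
"""

from __future__ import annotations

from . import nn
from .nn import Module, Tensor


class ConvBNSiLU(Module):
    """k x k convolution (no bias) -> batch norm -> SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, g: int = 1,
                 p: int | None = None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, padding=k // 2 if p is None else p,
                              groups=g, bias=False)
        self.bn = nn.BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    """1x1 reduce -> 3x3 conv, with optional residual add."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv2 = ConvBNSiLU(c_, c2, 3, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage-partial block: split, n bottlenecks, concat, 1x1 fuse."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True, e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv2 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv3 = ConvBNSiLU(2 * c_, c2, 1, 1)
        self.m = [Bottleneck(c_, c_, shortcut, e=1.0) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(nn.concat([y, self.cv2(x)], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained k x k max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv2 = ConvBNSiLU(c_ * 4, c2, 1, 1)
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        y1 = nn.max_pool2d(x, self.k, 1, self.k // 2)
        y2 = nn.max_pool2d(y1, self.k, 1, self.k // 2)
        y3 = nn.max_pool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(nn.concat([x, y1, y2, y3], axis=1))
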
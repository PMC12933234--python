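"""Weighted bidirectional feature fusion neck (GS-BiFPN).

The neck fuses the three backbone feature levels P3/P4/P5 (strides 8/16/32)
with one top-down and one bottom-up pass.  Each fusion node combines its
(resized) inputs by fast normalized weighting

    out = sum_i  w_i / (eps + sum_j w_j) * in_i,      w_i >= 0 learned,

the bidirectional-pyramid rule that replaces concatenation with a cheap
scalar-weighted sum.  Single-input nodes are removed from the graph; the
middle level (P4), the only one with both an intermediate and an output
node, carries an extra same-level skip edge from its input to its output
node.  All neck convolutions are GSConv, and the C3-style fuse blocks use
GSConv internally; bottom-up downsampling is a stride-2 GSConv.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import nn
from .blocks import ConvBNSiLU
from .dynamic_conv import GSConv
from .nn import Module, Tensor

__all__ = [
    "FusionError", "FusionNode", "fast_normalized_fusion", "resize_to",
    "GSC3", "GSBiFPN", "gs_bifpn_neck",
]


class FusionError(ValueError):
    """Raised when fusion inputs disagree in shape or count."""


class FusionNode(Module):
    """A weighted-fusion node: >= 2 inputs, learnable nonnegative weights.

    Nonnegativity is enforced by a ReLU projection of the raw weights before
    normalization.
    """

    def __init__(self, input_ids: Sequence[str], eps: float = 1e-4):
        super().__init__()
        if len(input_ids) < 2:
            raise FusionError(
                f"fusion node needs >= 2 inputs (single-input nodes are removed), "
                f"got {list(input_ids)}")
        if not eps > 0:
            raise FusionError("eps must be > 0")
        self.input_ids = list(input_ids)
        self.eps = eps
        self.weights = Tensor(np.ones(len(input_ids), np.float32), requires_grad=True)

    def coefficients(self) -> Tensor:
        w = self.weights.relu()
        return w * (w.sum() + self.eps).reciprocal()

    def forward(self, inputs: Sequence[Tensor]) -> Tensor:
        return fast_normalized_fusion(inputs, self)


def fast_normalized_fusion(inputs: Sequence[Tensor], node: FusionNode) -> Tensor:
    """Combine ``inputs`` with the node's normalized nonnegative weights."""
    if len(inputs) != len(node.input_ids):
        raise FusionError(f"expected {len(node.input_ids)} inputs, got {len(inputs)}")
    shapes = {tuple(t.shape) for t in inputs}
    if len(shapes) != 1:
        raise FusionError(f"fusion inputs must share a shape, got {sorted(shapes)}")
    coef = node.coefficients()
    out = inputs[0] * coef[0]
    for i in range(1, len(inputs)):
        out = out + inputs[i] * coef[i]
    return out


def resize_to(x: Tensor, target_hw: tuple[int, int]) -> Tensor:
    """Resize a feature map to an adjacent pyramid level's spatial shape.

    Upsampling is nearest-neighbor x2; downsampling is 2x2 max-pooling with
    stride 2.  Only the identity and exact x2 / /2 relations are supported.
    """
    h, w = x.shape[2], x.shape[3]
    th, tw = target_hw
    if (th, tw) == (h, w):
        return x
    if (th, tw) == (2 * h, 2 * w):
        return nn.upsample_nearest2x(x)
    if (h, w) == (2 * th, 2 * tw):
        return nn.max_pool2d(x, 2, 2, 0)
    raise FusionError(f"non-integral resize {h}x{w} -> {th}x{tw}")


class _GSBottleneck(Module):
    """Residual pair of GSConvs: 1x1 squeeze then 3x3, slim-neck style."""

    def __init__(self, c: int, dw_k: int = 5, k1: int = 1):
        super().__init__()
        self.gs1 = GSConv(c, c, k1, 1, dw_k)
        self.gs2 = GSConv(c, c, 3, 1, dw_k)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.gs2(self.gs1(x))


class GSC3(Module):
    """C3-style fuse block whose inner bottlenecks are GSConv pairs."""

    def __init__(self, c1: int, c2: int, n: int = 1, dw_k: int = 5, k1: int = 1):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv2 = ConvBNSiLU(c1, c_, 1, 1)
        self.cv3 = ConvBNSiLU(2 * c_, c2, 1, 1)
        self.m = [_GSBottleneck(c_, dw_k, k1) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(nn.concat([y, self.cv2(x)], axis=1))


class GSBiFPN(Module):
    """One (or more) bidirectional weighted-fusion layers over P3/P4/P5.

    Per repeat:

    * top-down:  td4 = GSC3(fuse(up(lat5(P5)), P4));  N3 = GSC3(fuse(up(lat4(td4)), P3))
    * bottom-up: N4 = GSC3(fuse(down(N3), td4, P4))   (P4 skip edge)
    *            N5 = GSC3(fuse(down(N4), P5))

    Channel widths per level are preserved (c3/c4/c5), so outputs are
    drop-in replacements for the plain path-aggregation neck.
    """

    def __init__(self, c3: int, c4: int, c5: int, repeats: int = 1,
                 dw_k: int = 5, n_blocks: int = 1, k1: int = 1):
        super().__init__()
        self.channels = (c3, c4, c5)
        self.repeats = repeats
        self.lat5 = [GSConv(c5, c4, 1, 1, dw_k) for _ in range(repeats)]
        self.lat4 = [GSConv(c4, c3, 1, 1, dw_k) for _ in range(repeats)]
        self.down3 = [GSConv(c3, c4, 3, 2, dw_k) for _ in range(repeats)]
        self.down4 = [GSConv(c4, c5, 3, 2, dw_k) for _ in range(repeats)]
        self.blk_td4 = [GSC3(c4, c4, n_blocks, dw_k, k1) for _ in range(repeats)]
        self.blk_n3 = [GSC3(c3, c3, n_blocks, dw_k, k1) for _ in range(repeats)]
        self.blk_n4 = [GSC3(c4, c4, n_blocks, dw_k, k1) for _ in range(repeats)]
        self.blk_n5 = [GSC3(c5, c5, n_blocks, dw_k, k1) for _ in range(repeats)]
        self.fuse_td4 = [FusionNode(["up(P5)", "P4"]) for _ in range(repeats)]
        self.fuse_n3 = [FusionNode(["up(td4)", "P3"]) for _ in range(repeats)]
        self.fuse_n4 = [FusionNode(["down(N3)", "td4", "P4"]) for _ in range(repeats)]
        self.fuse_n5 = [FusionNode(["down(N4)", "P5"]) for _ in range(repeats)]

    def forward(self, p3: Tensor, p4: Tensor, p5: Tensor):
        for r in range(self.repeats):
            hw4 = (p4.shape[2], p4.shape[3])
            hw3 = (p3.shape[2], p3.shape[3])
            t5 = self.lat5[r](p5)
            td4 = self.blk_td4[r](self.fuse_td4[r]([resize_to(t5, hw4), p4]))
            t4 = self.lat4[r](td4)
            n3 = self.blk_n3[r](self.fuse_n3[r]([resize_to(t4, hw3), p3]))
            n4 = self.blk_n4[r](self.fuse_n4[r]([self.down3[r](n3), td4, p4]))
            n5 = self.blk_n5[r](self.fuse_n5[r]([self.down4[r](n4), p5]))
            p3, p4, p5 = n3, n4, n5
        return p3, p4, p5


def gs_bifpn_neck(p3: Tensor, p4: Tensor, p5: Tensor, neck: GSBiFPN):
    """Run a :class:`GSBiFPN` neck on the three backbone levels."""
    return neck(p3, p4, p5)
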
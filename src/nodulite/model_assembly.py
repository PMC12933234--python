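"""Detector assembly: baseline CSP detector and the improved variant.

The baseline is the standard small CSP detector (YOLOv5s layout): a CSP
backbone with four C3 stages and an SPPF tail, a path-aggregation neck, and
a three-level anchor head.  Two independent toggles produce the improved
model of this package:

* ``use_c3_odc``   — backbone C3 stages become :class:`~nodulite.dynamic_conv.C3_ODC`
  (bottleneck convolutions replaced by omni-dimensional dynamic convolution);
* ``use_gs_bifpn`` — the neck becomes the weighted bidirectional GS-BiFPN.

``loss_mode`` selects the training objective (``ciou`` baseline or the
focal+NWD ``f_nwd``) and is carried here so one config object describes a
full ablation cell; all 8 toggle combinations are valid.

Accounting: ``count_params`` is the exact number of trainable scalars;
``count_flops`` measures one forward pass at the given input size and counts
2 FLOPs per multiply-accumulate over convolution and linear layers
(attention branches included), reported in GFLOPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from . import nn
from .blocks import C3, SPPF, ConvBNSiLU
from .dynamic_conv import C3_ODC
from .neck_fusion import GSBiFPN
from .nn import Module, Tensor

__all__ = [
    "ModelConfig", "Detector", "build_detector", "count_params", "count_flops",
    "reference_improved_config", "load_config", "save_config", "DEFAULT_ANCHORS",
]

#: default anchors (w, h in input pixels) for strides 8 / 16 / 32
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)

STRIDES = (8, 16, 32)


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(int(math.ceil(x / divisor) * divisor), divisor)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration (one ablation cell).

    The ``odconv_*`` and ``gs_*`` fields are the shipped reference values
    for the improved model; see :func:`reference_improved_config`.
    """

    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    num_classes: int = 1
    input_size: int = 640
    use_c3_odc: bool = False
    use_gs_bifpn: bool = False
    loss_mode: str = "ciou"  # or "f_nwd"
    anchors: tuple = DEFAULT_ANCHORS
    # C3_ODC knobs (reference calibration: single kernel, reduction 3,
    # 1x1 reduce convs replaced as well)
    odconv_n_kernels: int = 1
    odconv_reduction: int = 3
    odconv_replace_1x1: bool = True
    odconv_kernel_softmax: bool = False
    odconv_stages: tuple = (0, 1, 2, 3)  # which backbone C3 stages
    # GS-BiFPN knobs (reference calibration: depthwise kernel 9)
    gs_dw_k: int = 9
    bifpn_repeats: int = 1
    gsc3_n: int = 1
    gsc3_k1: int = 1  # kernel of the first GSConv inside each GSC3 bottleneck
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.loss_mode not in ("ciou", "f_nwd"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")

    def widths(self) -> list[int]:
        return [make_divisible(c * self.width_multiple) for c in (64, 128, 256, 512, 1024)]

    def depth(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1)


def reference_improved_config(**overrides) -> ModelConfig:
    """The shipped improved-model configuration (both toggles on, F-NWD).

    The ODConv capacity (number of kernels, attention reduction ratio,
    1x1-replacement) and the GSConv depthwise kernel were calibrated once
    for this reference model and are part of the package defaults.
    """
    base = ModelConfig(use_c3_odc=True, use_gs_bifpn=True, loss_mode="f_nwd")
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# sub-networks
# ---------------------------------------------------------------------------


class Backbone(Module):
    """CSP backbone: stem + four stage convs, C3 (or C3_ODC) blocks, SPPF."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        w = cfg.widths()  # [32, 64, 128, 256, 512] at width 0.5
        d = cfg.depth

        def c3_block(stage_idx: int, c1: int, c2: int, n: int):
            if cfg.use_c3_odc and stage_idx in cfg.odconv_stages:
                return C3_ODC(c1, c2, n, True,
                              n_kernels=cfg.odconv_n_kernels,
                              reduction_ratio=cfg.odconv_reduction,
                              replace_1x1=cfg.odconv_replace_1x1,
                              kernel_softmax=cfg.odconv_kernel_softmax)
            return C3(c1, c2, n, True)

        self.stem = ConvBNSiLU(3, w[0], 6, 2, p=2)
        self.cv1 = ConvBNSiLU(w[0], w[1], 3, 2)
        self.c3_1 = c3_block(0, w[1], w[1], d(3))
        self.cv2 = ConvBNSiLU(w[1], w[2], 3, 2)
        self.c3_2 = c3_block(1, w[2], w[2], d(6))
        self.cv3 = ConvBNSiLU(w[2], w[3], 3, 2)
        self.c3_3 = c3_block(2, w[3], w[3], d(9))
        self.cv4 = ConvBNSiLU(w[3], w[4], 3, 2)
        self.c3_4 = c3_block(3, w[4], w[4], d(3))
        self.sppf = SPPF(w[4], w[4], 5)

    def forward(self, x: Tensor):
        x = self.cv1(self.stem(x))
        x = self.c3_1(x)
        p3 = self.c3_2(self.cv2(x))
        p4 = self.c3_3(self.cv3(p3))
        p5 = self.sppf(self.c3_4(self.cv4(p4)))
        return p3, p4, p5


class PANetNeck(Module):
    """Plain path-aggregation neck (baseline): concat fusion, dense convs."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        w = cfg.widths()
        c3_, c4_, c5_ = w[2], w[3], w[4]
        d = cfg.depth
        self.lat5 = ConvBNSiLU(c5_, c4_, 1, 1)
        self.td4 = C3(2 * c4_, c4_, d(3), False)
        self.lat4 = ConvBNSiLU(c4_, c3_, 1, 1)
        self.out3 = C3(2 * c3_, c3_, d(3), False)
        self.down3 = ConvBNSiLU(c3_, c3_, 3, 2)
        self.out4 = C3(2 * c3_, c4_, d(3), False)
        self.down4 = ConvBNSiLU(c4_, c4_, 3, 2)
        self.out5 = C3(2 * c4_, c5_, d(3), False)

    def forward(self, p3: Tensor, p4: Tensor, p5: Tensor):
        t5 = self.lat5(p5)
        td4 = self.td4(nn.concat([nn.upsample_nearest2x(t5), p4], axis=1))
        t4 = self.lat4(td4)
        n3 = self.out3(nn.concat([nn.upsample_nearest2x(t4), p3], axis=1))
        n4 = self.out4(nn.concat([self.down3(n3), t4], axis=1))
        n5 = self.out5(nn.concat([self.down4(n4), t5], axis=1))
        return n3, n4, n5


class Detect(Module):
    """Three-level anchor head: one 1x1 prediction conv per level.

    Each level predicts ``na * (5 + nc)`` channels (box 4, objectness 1,
    classes nc).  Objectness biases are initialized to the standard prior
    (about 8 objects per 640^2 image) to stabilize early training.
    """

    def __init__(self, channels: tuple[int, int, int], cfg: ModelConfig):
        super().__init__()
        self.nc = cfg.num_classes
        self.na = len(cfg.anchors[0])
        self.no = 5 + self.nc
        self.anchors = np.asarray(cfg.anchors, dtype=np.float32)
        self.strides = np.asarray(STRIDES, dtype=np.float32)
        self.convs = [nn.Conv2d(c, self.na * self.no, 1, bias=True) for c in channels]
        for conv, s in zip(self.convs, STRIDES):
            b = conv.bias.data.reshape(self.na, self.no)
            b[:, 4] += math.log(8.0 / (640.0 / s) ** 2)
            if self.nc > 1:
                b[:, 5:] += math.log(0.6 / (self.nc - 0.99))

    def forward(self, feats):
        return [conv(f) for conv, f in zip(self.convs, feats)]


class Detector(Module):
    """Backbone + neck + head; forward returns raw per-level prediction maps."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.widths()
        self.backbone = Backbone(cfg)
        if cfg.use_gs_bifpn:
            self.neck = GSBiFPN(w[2], w[3], w[4], cfg.bifpn_repeats,
                                cfg.gs_dw_k, cfg.gsc3_n, cfg.gsc3_k1)
        else:
            self.neck = PANetNeck(cfg)
        self.head = Detect((w[2], w[3], w[4]), cfg)

    def forward(self, x: Tensor):
        p3, p4, p5 = self.backbone(x)
        n3, n4, n5 = self.neck(p3, p4, p5)
        return self.head([n3, n4, n5])


def build_detector(cfg: ModelConfig) -> Detector:
    """Construct a detector for one ablation cell, with seeded init."""
    nn.seed_init(cfg.seed)
    return Detector(cfg)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------


def count_params(det: Module) -> int:
    """Exact number of trainable scalars."""
    return det.num_parameters()


def count_flops(det: Detector, input_size: int | None = None) -> float:
    """GFLOPs of one forward pass at ``input_size`` (2 FLOPs per MAC).

    Counts multiply-accumulates of convolution and linear layers only,
    including the dynamic-convolution attention branches; batch norm and
    activations are excluded, following the usual detector-accounting
    convention.
    """
    s = input_size or det.cfg.input_size
    was_training = det.training
    det.eval()
    x = Tensor(np.zeros((1, 3, s, s), np.float32))
    with nn.no_grad(), nn.profile():
        det(x)
        macs = nn.profiled_macs()
    if was_training:
        det.train()
    return 2.0 * macs / 1e9


# ---------------------------------------------------------------------------
# config file IO
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"anchors", "odconv_stages"}


def load_config(path) -> ModelConfig:
    """Read a ModelConfig from a YAML key/value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    for k, v in raw.items():
        if k == "anchors":
            v = tuple(tuple(tuple(p) for p in lvl) for lvl in v)
        elif k in _TUPLE_FIELDS:
            v = tuple(v)
        kw[k] = v
    return ModelConfig(**kw)


def save_config(cfg: ModelConfig, path) -> None:
    d = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    d["anchors"] = [[list(p) for p in lvl] for lvl in cfg.anchors]
    d["odconv_stages"] = list(cfg.odconv_stages)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
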
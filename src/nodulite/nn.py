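"""Minimal numpy autograd and neural-network layer library.

This is the compute core the detector is built on: a reverse-mode autograd
``Tensor`` over float32 numpy arrays, the handful of layer types a YOLO-style
detector needs (convolution via im2col + BLAS matmul, batch norm, SiLU,
max-pool, nearest upsampling, linear), and a momentum-SGD optimizer.

Design notes
------------
* Gradients are accumulated by a topological-sort backward pass
  (``Tensor.backward``).  Broadcasting in elementwise ops is undone by
  summing over the broadcast axes.
* Convolution supports ``groups in {1, in_channels}`` (standard and
  depthwise), which is all the architecture uses.
* A process-global MAC counter (``profile`` context manager) lets callers
  measure the multiply-accumulate cost of a forward pass; only convolution
  and linear layers count, at the conventional 2 FLOPs per MAC.
"""

from __future__ import annotations

import contextlib
from typing import Iterator, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# global modes
# ---------------------------------------------------------------------------

_GRAD_ENABLED = True
_PROFILE = False
_MACS = 0


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def profile():
    """Count multiply-accumulates of conv/linear layers inside the block."""
    global _PROFILE, _MACS
    _PROFILE, _MACS = True, 0
    try:
        yield
    finally:
        _PROFILE = False


def profiled_macs() -> int:
    """MACs accumulated by the most recent ``profile()`` block."""
    return _MACS


def _count_macs(n: int) -> None:
    global _MACS
    if _PROFILE:
        _MACS += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph machinery -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references so intermediate buffers can be collected
        for node in topo:
            node._backward = None
            node._prev = ()

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.reciprocal()

    def __rtruediv__(self, other):
        return Tensor(other) * self.reciprocal()

    def reciprocal(self):
        out_data = 1.0 / self.data

        def bwd(g):
            if self.requires_grad:
                self._accum(-g * out_data * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bwd(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), bwd)

    def atan(self):
        out_data = np.arctan(self.data)

        def bwd(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(out_data, (self,), bwd)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.shape

        def bwd(g):
            self._accum(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    def matmul(self, other: "Tensor"):
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bwd)


# -- free functions on tensors ----------------------------------------------


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.minimum(a.data, b.data)
    mask = (a.data <= b.data).astype(np.float32)

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.shape))

    return Tensor._make(out_data, (a, b), bwd)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.maximum(a.data, b.data)
    mask = (a.data >= b.data).astype(np.float32)

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.shape))

    return Tensor._make(out_data, (a, b), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    return concat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors], axis=axis)


# ---------------------------------------------------------------------------
# convolution primitives (im2col)
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B, C*k*k, ho*wo) patch matrix."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, ho, wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(b, c * k * k, ho * wo)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    b, c, h, w = x_shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    dcols = dcols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``groups`` must be 1 (dense) or equal to the input channel count
    (depthwise with one filter per channel).
    """
    b, cin, h, w = x.shape
    cout, cin_g, k, _ = weight.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data

    if groups == 1:
        assert cin_g == cin, "channel mismatch"
        cols = _im2col(xp, k, stride, ho, wo)              # (B, Cin*k*k, L)
        wmat = weight.data.reshape(cout, cin * k * k)
        out_data = np.matmul(wmat[None], cols)             # (B, Cout, L)
        _count_macs(b * cout * cin * k * k * ho * wo)
    elif groups == cin and cout == cin and cin_g == 1:
        cols = _im2col(xp, k, stride, ho, wo).reshape(b, cin, k * k, ho * wo)
        wmat = weight.data.reshape(cin, k * k)
        out_data = np.einsum("bckl,ck->bcl", cols, wmat)
        _count_macs(b * cin * k * k * ho * wo)
    else:
        raise ValueError(f"unsupported groups={groups} for cin={cin}, cout={cout}")

    out_data = out_data.reshape(b, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gm = g.reshape(b, cout, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gm.sum(axis=(0, 2)))
        if groups == 1:
            if weight.requires_grad:
                # sum_b g_b @ cols_b^T, as a batched BLAS matmul
                dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accum(dw.reshape(weight.shape))
            if x.requires_grad:
                dcols = np.matmul(wmat.T[None], gm)        # (B, Cin*k*k, L)
                x._accum(_col2im(dcols, x.shape, k, stride, padding, ho, wo))
        else:
            gmc = gm.reshape(b, cin, 1, ho * wo)
            if weight.requires_grad:
                dw = (gmc * cols).sum(axis=(0, 3))         # (Cin, k*k) after squeeze
                weight._accum(dw.reshape(weight.shape))
            if x.requires_grad:
                dcols = wmat[None, :, :, None] * gmc       # (B, Cin, k*k, L)
                x._accum(_col2im(dcols, x.shape, k, stride, padding, ho, wo))

    return Tensor._make(out_data, parents, bwd)


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    b, c, h, w = x.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    cols = _im2col(xp, k, stride, ho, wo).reshape(b, c, k * k, ho * wo)
    arg = cols.argmax(axis=2)
    out_data = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0].reshape(b, c, ho, wo)

    def bwd(g):
        gm = g.reshape(b, c, 1, ho * wo)
        dcols = np.zeros((b, c, k * k, ho * wo), dtype=np.float32)
        np.put_along_axis(dcols, arg[:, :, None], gm, axis=2)
        dxp = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=np.float32)
        dc = dcols.reshape(b, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dc[:, :, i, j]
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return Tensor._make(out_data, (x,), bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    b, c, h, w = x.shape

    def bwd(g):
        x._accum(g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery, train/eval mode, state IO."""

    def __init__(self):
        self.training = True

    def forward(self, *a, **kw):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)

    def _children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + name, v
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_parameters(prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # plain-dict checkpointing (text-friendly via np.savez elsewhere)
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, v in self.__dict__.items():
            if isinstance(v, BatchNorm2d):
                out[name + ".running_mean"] = v.running_mean.copy()
                out[name + ".running_var"] = v.running_var.copy()
        for name, v in self.__dict__.items():
            if isinstance(v, Module) and not isinstance(v, BatchNorm2d):
                for k, arr in v.state_dict().items():
                    if k.endswith("running_mean") or k.endswith("running_var"):
                        out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            if k.endswith("running_mean") or k.endswith("running_var"):
                                out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, arr in state.items():
            if k in params:
                params[k].data[...] = arr
            elif k.endswith("running_mean") or k.endswith("running_var"):
                obj = self
                parts = k.split(".")
                for p in parts[:-1]:
                    obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
                setattr(obj, parts[-1], arr.astype(np.float32).copy())


def _kaiming(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    bound = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the parameter-initialization stream (model builds are seeded)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        self.weight = Tensor(_kaiming((cout, cin // groups, k, k), fan_in, _INIT_RNG),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            with np.errstate(all="ignore"):
                self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
                unbiased = var.data.ravel() * n / max(n - 1, 1)
                self.running_var += self.momentum * (unbiased - self.running_var)
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, self.c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, self.c, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.weight.reshape(1, self.c, 1, 1) + self.bias.reshape(1, self.c, 1, 1)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.weight = Tensor(_kaiming((cin, cout), cin, _INIT_RNG), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        _count_macs(int(np.prod(x.shape[:-1])) * self.cin * self.cout)
        out = x.matmul(self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.bufs = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, buf in zip(self.params, self.bufs):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf
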
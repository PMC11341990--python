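"""Reverse-mode automatic differentiation over numpy arrays.

A small tensor engine in the micrograd style: every operation records its
inputs and a backward closure; :meth:`Tensor.backward` runs the tape in
reverse topological order.  Arrays are kept in float32 throughout.  Only the
operations the detector needs are provided — dense/grouped/depthwise 2-D
convolution, pooling, nearest upsampling, window unfolding (for content-aware
reassembly), matmul, softmax and elementwise arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "Parameter", "cat", "stack", "no_grad", "count_macs"]

_grad_enabled = [True]
_mac_counter: list = []  # stack of active accumulators


class no_grad:
    """Context manager: skip recording the backward tape (inference mode)."""

    def __enter__(self):
        self._prev = _grad_enabled[0]
        _grad_enabled[0] = False
        return self

    def __exit__(self, *exc):
        _grad_enabled[0] = self._prev
        return False


class count_macs:
    """Count floating-point operations executed by conv2d/matmul while the
    context is active (one multiply-accumulate = 2 ops, one bias add = 1);
    read the total from ``.total`` afterwards."""

    def __enter__(self):
        self.total = 0
        _mac_counter.append(self)
        return self

    def __exit__(self, *exc):
        _mac_counter.remove(self)
        return False


def _add_flops(n: int):
    for c in _mac_counter:
        c.total += n


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(_as_array(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _sum_to_shape(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def atan(self):
        def bwd(g):
            self._accumulate(g / (1.0 + self.data**2))

        return Tensor._make(np.arctan(self.data), (self,), bwd)

    def sigmoid(self):
        s = expit(self.data)

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def silu(self):
        s = expit(self.data)

        def bwd(g):
            self._accumulate(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(self.data * s, (self,), bwd)

    def batchnorm_train(self, weight: "Tensor", bias: "Tensor", eps: float):
        """Fused batch normalisation over (N, H, W) with per-channel affine;
        returns (out, batch_mean, batch_var) — the statistics as arrays."""
        x = self.data
        n = x.shape[0] * x.shape[2] * x.shape[3]
        mu = x.mean(axis=(0, 2, 3))
        xc = x - mu.reshape(1, -1, 1, 1)
        var = np.einsum("bchw,bchw->c", xc, xc) / n
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv.reshape(1, -1, 1, 1)
        out = xhat * weight.data.reshape(1, -1, 1, 1) + bias.data.reshape(1, -1, 1, 1)

        def bwd(g):
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                weight._accumulate(np.einsum("bchw,bchw->c", g, xhat))
            if self.requires_grad:
                dxhat = g * weight.data.reshape(1, -1, 1, 1)
                s1 = dxhat.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
                s2 = np.einsum("bchw,bchw->c", dxhat, xhat).reshape(1, -1, 1, 1)
                dx = (dxhat - s1 / n - xhat * s2 / n) * inv.reshape(1, -1, 1, 1)
                self._accumulate(dx)

        return Tensor._make(out, (self, weight, bias), bwd), mu, var

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data >= other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * mask, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * ~mask, other.data.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), bwd)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data <= other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * mask, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * ~mask, other.data.shape))

        return Tensor._make(np.minimum(self.data, other.data), (self, other), bwd)

    def clamp(self, lo=None, hi=None):
        out = self
        if lo is not None:
            out = out.maximum(Tensor(np.float32(lo)))
        if hi is not None:
            out = out.minimum(Tensor(np.float32(hi)))
        return out

    # -- reductions / shape ops --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * mask / np.maximum(mask.sum(axis=axis, keepdims=True), 1))

        return Tensor._make(out_data if keepdims else out_data.squeeze(axis), (self,), bwd)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    def pad2d(self, pad: int, value: float = 0.0):
        """Zero/constant padding of the two trailing spatial axes (NCHW)."""
        if pad == 0:
            return self
        pw = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]

        def bwd(g):
            sl = tuple([slice(None)] * (self.data.ndim - 2) + [slice(pad, -pad)] * 2)
            self._accumulate(g[sl])

        return Tensor._make(
            np.pad(self.data, pw, constant_values=np.float32(value)), (self,), bwd
        )

    # -- linear algebra -----------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = other if isinstance(other, Tensor) else Tensor(other)
        if _mac_counter:
            out_shape = np.broadcast_shapes(self.data.shape[:-2], other.data.shape[:-2])
            _add_flops(
                2 * int(np.prod(out_shape, dtype=np.int64))
                * self.data.shape[-2] * self.data.shape[-1] * other.data.shape[-1]
            )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(
                    _sum_to_shape(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _sum_to_shape(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        return Tensor._make(s, (self,), bwd)

    def bce_with_logits(self, target: np.ndarray):
        """Elementwise binary cross entropy on logits (numerically stable)."""
        x, t = self.data, _as_array(target)
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

        def bwd(g):
            self._accumulate(g * (1.0 / (1.0 + np.exp(-x)) - t))

        return Tensor._make(loss, (self,), bwd)

    # -- spatial ops --------------------------------------------------------
    @staticmethod
    def _windows(xp: np.ndarray, kh, kw, sh, sw):
        b, c, hp, wp = xp.shape
        ho, wo = (hp - kh) // sh + 1, (wp - kw) // sw + 1
        st = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp,
            (b, c, ho, wo, kh, kw),
            (st[0], st[1], st[2] * sh, st[3] * sw, st[2], st[3]),
            writeable=False,
        )
        return view, ho, wo

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1):
        """2-D cross-correlation, NCHW; weight (Co, Ci/g, kh, kw)."""
        x = self.data
        co, cig, kh, kw = weight.data.shape
        b, ci, _, _ = x.shape
        if ci != cig * groups:
            raise ValueError(f"conv2d channel mismatch: {ci} vs {cig}*{groups}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) if padding else x
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        if _mac_counter:
            _add_flops(2 * b * co * ho * wo * cig * kh * kw
                       + (b * co * ho * wo if bias is not None else 0))
        depthwise = groups == ci and co == ci

        def tap(i, j):
            return xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]

        # per-tap GEMM accumulation: no im2col materialisation
        if depthwise:
            w2 = weight.data[:, 0]
            out = np.zeros((b, co, ho, wo), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    out += tap(i, j) * w2[:, i, j].reshape(1, -1, 1, 1)
        elif groups == 1:
            acc = np.zeros((b, ho, wo, co), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    acc += np.tensordot(tap(i, j), weight.data[:, :, i, j],
                                        axes=([1], [1]))
            out = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
        else:
            cog = co // groups
            acc = np.zeros((b, ho, wo, co), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    ts = tap(i, j)
                    for g_ in range(groups):
                        acc[..., g_ * cog:(g_ + 1) * cog] += np.tensordot(
                            ts[:, g_ * cig:(g_ + 1) * cig],
                            weight.data[g_ * cog:(g_ + 1) * cog, :, i, j],
                            axes=([1], [1]))
            out = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
        if bias is not None:
            out += bias.data.reshape(1, -1, 1, 1)

        def bwd(g):
            g = np.ascontiguousarray(g)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            need_dx = self.requires_grad
            dxp = np.zeros_like(xp) if need_dx else None
            dw = np.zeros_like(weight.data) if weight.requires_grad else None
            for i in range(kh):
                for j in range(kw):
                    ts = tap(i, j)
                    if depthwise:
                        if dw is not None:
                            dw[:, 0, i, j] = (ts * g).sum(axis=(0, 2, 3))
                        if need_dx:
                            dxp[:, :, i:i + stride * ho:stride,
                                j:j + stride * wo:stride] += (
                                g * weight.data[:, 0, i, j].reshape(1, -1, 1, 1))
                    elif groups == 1:
                        if dw is not None:
                            dw[:, :, i, j] = np.tensordot(g, ts, axes=([0, 2, 3],
                                                                       [0, 2, 3]))
                        if need_dx:
                            d = np.tensordot(g, weight.data[:, :, i, j],
                                             axes=([1], [0]))
                            dxp[:, :, i:i + stride * ho:stride,
                                j:j + stride * wo:stride] += d.transpose(0, 3, 1, 2)
                    else:
                        cog = co // groups
                        for g_ in range(groups):
                            gs_ = g[:, g_ * cog:(g_ + 1) * cog]
                            if dw is not None:
                                dw[g_ * cog:(g_ + 1) * cog, :, i, j] = np.tensordot(
                                    gs_, ts[:, g_ * cig:(g_ + 1) * cig],
                                    axes=([0, 2, 3], [0, 2, 3]))
                            if need_dx:
                                d = np.tensordot(
                                    gs_, weight.data[g_ * cog:(g_ + 1) * cog, :, i, j],
                                    axes=([1], [0]))
                                dxp[:, g_ * cig:(g_ + 1) * cig,
                                    i:i + stride * ho:stride,
                                    j:j + stride * wo:stride] += d.transpose(0, 3, 1, 2)
            if dw is not None:
                weight._accumulate(dw)
            if need_dx:
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, bwd)

    def maxpool2d(self, kernel: int, stride: int | None = None, padding: int = 0):
        stride = stride or kernel
        x = self.data
        xp = (
            np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                   constant_values=np.float32(-np.inf))
            if padding else x
        )
        win, ho, wo = Tensor._windows(xp, kernel, kernel, stride, stride)
        out = win.max(axis=(4, 5))

        def bwd(g):
            dxp = np.zeros_like(xp)
            # distribute to (first occurrences of) the max; ties are measure-zero
            remaining = np.ones_like(out, dtype=bool)
            for i in range(kernel):
                for j in range(kernel):
                    sl = (slice(None), slice(None),
                          slice(i, i + stride * ho, stride),
                          slice(j, j + stride * wo, stride))
                    hit = remaining & (xp[sl] == out)
                    dxp[sl] += g * hit
                    remaining &= ~hit
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            self._accumulate(dxp)

        return Tensor._make(out, (self,), bwd)

    def upsample_nearest(self, scale: int):
        out = self.data.repeat(scale, axis=2).repeat(scale, axis=3)

        def bwd(g):
            b, c, h, w = self.data.shape
            self._accumulate(
                g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
            )

        return Tensor._make(out, (self,), bwd)

    def unfold_windows(self, kernel: int):
        """Same-padded k x k neighborhoods: (B,C,H,W) -> (B,C,k*k,H,W)."""
        pad = kernel // 2
        x = self.data
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2))
        win, _, _ = Tensor._windows(xp, kernel, kernel, 1, 1)
        out = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
            b, c, kernel * kernel, h, w
        )

        def bwd(g):
            g = g.reshape(b, c, kernel, kernel, h, w)
            dxp = np.zeros_like(xp)
            for i in range(kernel):
                for j in range(kernel):
                    dxp[:, :, i:i + h, j:j + w] += g[:, :, i, j]
            self._accumulate(dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp)

        return Tensor._make(out, (self,), bwd)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def cat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def stack(tensors: list, axis: int = 0) -> Tensor:
    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bwd)
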
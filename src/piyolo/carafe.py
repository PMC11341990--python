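"""CARAFE: content-aware reassembly of features for upsampling.

Instead of copying the nearest source pixel, CARAFE predicts — from the
feature content itself — a normalised ``kup x kup`` kernel for every output
location and reassembles the upsampled value as a convex combination of the
source neighborhood.  Two stages:

1. *kernel prediction*: a 1x1 conv compresses C channels to ``Cm``, a
   ``kenc x kenc`` encoder conv emits ``sigma^2 * kup^2`` channels, which are
   rearranged channel-to-space into a ``sigma*H x sigma*W x kup^2`` field and
   softmax-normalised over the ``kup^2`` axis;
2. *reassembly*: output pixel (i', j') is the dot product of its kernel with
   the ``kup x kup`` window of the input centred at (i'//sigma, j'//sigma).
   All channels at one location share the same kernel.

Functional numpy operators mirror the autodiff :class:`CARAFE` module used in
the detector neck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "CarafeConfig", "CarafeParams", "predict_kernels", "reassemble",
    "carafe_upsample", "CARAFE",
]


@dataclass
class CarafeConfig:
    """``Cm``: compressed channels; ``sigma``: integer upsampling factor;
    ``kup``: odd reassembly kernel; ``kenc``: odd encoder kernel."""

    Cm: int = 64
    sigma: int = 2
    kup: int = 5
    kenc: int = 3

    def validate(self, c: int | None = None):
        if self.sigma < 1:
            raise ValueError("sigma must be >= 1")
        if self.kup % 2 == 0 or self.kenc % 2 == 0:
            raise ValueError("kup and kenc must be odd")
        if c is not None and self.Cm > c:
            raise ValueError(f"Cm={self.Cm} exceeds input channels {c}")


@dataclass
class CarafeParams:
    """Compressor (1x1, C->Cm) and encoder (kenc, Cm -> sigma^2*kup^2),
    both with biases."""

    w_comp: np.ndarray   # (Cm, C, 1, 1)
    b_comp: np.ndarray
    w_enc: np.ndarray    # (sigma^2*kup^2, Cm, kenc, kenc)
    b_enc: np.ndarray


def _conv2d_ref(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Plain same-padded HWC convolution used by the functional path."""
    co, ci, k, _ = w.shape
    h, wd, _ = x.shape
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((h, wd, co))
    for i in range(k):
        for j in range(k):
            out += xp[i:i + h, j:j + wd] @ w[:, :, i, j].T
    return out + b


def predict_kernels(X: np.ndarray, cfg: CarafeConfig,
                    params: CarafeParams) -> np.ndarray:
    """Predict normalised reassembly kernels, shape (sigma*H, sigma*W, kup^2).

    The encoder output's sigma^2 * kup^2 channels are spread channel-to-space:
    the sigma x sigma sub-pixel block at source pixel (i, j) is filled in
    row-major order, so output (sigma*i + di, sigma*j + dj) takes the kup^2
    kernel from channel block di*sigma + dj.  Softmax over the kup^2 axis makes
    every kernel nonnegative with unit sum.
    """
    h, w, c = X.shape
    cfg.validate(c)
    comp = _conv2d_ref(X, params.w_comp, params.b_comp)
    enc = _conv2d_ref(comp, params.w_enc, params.b_enc)  # (H, W, s^2*kup^2)
    s, k2 = cfg.sigma, cfg.kup**2
    enc = enc.reshape(h, w, s, s, k2)
    kern = enc.transpose(0, 2, 1, 3, 4).reshape(s * h, s * w, k2)
    kern = kern - kern.max(axis=-1, keepdims=True)
    np.exp(kern, out=kern)
    kern /= kern.sum(axis=-1, keepdims=True)
    return kern


def reassemble(X: np.ndarray, kernels: np.ndarray, cfg: CarafeConfig) -> np.ndarray:
    """Content-aware reassembly: convex combinations of kup x kup windows."""
    h, w, c = X.shape
    s, kup = cfg.sigma, cfg.kup
    if kernels.shape != (s * h, s * w, kup * kup):
        raise ValueError(f"kernel field shape {kernels.shape} inconsistent "
                         f"with input {X.shape} at sigma={s}")
    pad = kup // 2
    xp = np.pad(X, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((s * h, s * w, c))
    ii = np.arange(s * h) // s
    jj = np.arange(s * w) // s
    for di in range(kup):
        for dj in range(kup):
            win = xp[ii[:, None] + di, jj[None, :] + dj]       # (sH, sW, C)
            out += win * kernels[:, :, di * kup + dj, None]
    return out


def carafe_upsample(X: np.ndarray, cfg: CarafeConfig,
                    params: CarafeParams) -> np.ndarray:
    """Kernel prediction followed by reassembly: (H,W,C) -> (sH,sW,C)."""
    return reassemble(X, predict_kernels(X, cfg, params), cfg)


class CARAFE(nn.Module):
    """Autodiff CARAFE upsampler for NCHW tensors (drop-in for nearest x2)."""

    def __init__(self, c: int, cfg: CarafeConfig | None = None):
        super().__init__()
        self.cfg = cfg or CarafeConfig()
        self.cfg.validate(c)
        self.c = c
        s2k2 = self.cfg.sigma**2 * self.cfg.kup**2
        self.comp = nn.Conv2d(c, self.cfg.Cm, 1, bias=True)
        self.enc = nn.Conv2d(self.cfg.Cm, s2k2, self.cfg.kenc, bias=True)

    def predict_kernels(self, x: Tensor) -> Tensor:
        """Normalised kernels as a tensor of shape (B, sigma^2, kup^2, H, W)."""
        b, c, h, w = x.shape
        s, k2 = self.cfg.sigma, self.cfg.kup**2
        enc = self.enc(self.comp(x))                     # (B, s^2*k^2, H, W)
        kern = enc.reshape(b, s * s, k2, h, w)
        return kern.softmax(axis=2)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        s, kup = self.cfg.sigma, self.cfg.kup
        kern = self.predict_kernels(x)                   # (B, s^2, k^2, H, W)
        win = x.unfold_windows(kup)                      # (B, C, k^2, H, W)
        from .nn import tensor as _t
        if _t._mac_counter:
            _t._add_flops(2 * b * c * s * s * kup * kup * h * w)
        # (B,1,s^2,k^2,H,W) * (B,C,1,k^2,H,W) summed over k^2
        prod = win.reshape(b, c, 1, kup * kup, h, w) * kern.reshape(
            b, 1, s * s, kup * kup, h, w
        )
        out = prod.sum(axis=3)                           # (B, C, s^2, H, W)
        # sub-pixel shuffle: (B, C, s, s, H, W) -> (B, C, H, s, W, s)
        out = out.reshape(b, c, s, s, h, w).transpose(0, 1, 4, 2, 5, 3)
        return out.reshape(b, c, s * h, s * w)
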
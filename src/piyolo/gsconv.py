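"""GSConv: half-dense, half-depthwise convolution with channel shuffle.

A GSConv layer spends a standard convolution on only half of its output
channels; the other half is produced by a cheap depthwise convolution of the
first half.  Concatenating the two halves and shuffling the channels (group
interleave, two groups) mixes dense and depthwise information uniformly while
roughly halving the parameter count of the layer.  The ELAN-GS neck block
swaps the four pre-concatenation convolutions of a standard ELAN aggregation
block for GSConv.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, cat

__all__ = ["GSConvConfig", "channel_shuffle", "shuffle_permutation", "GSConv"]


@dataclass
class GSConvConfig:
    c1: int
    c2: int
    k: int = 1
    s: int = 1
    dw_kernel: int = 5

    def validate(self):
        if self.c2 % 2:
            raise ValueError("GSConv output channels must be even")
        if self.k % 2 == 0 or self.dw_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")


def shuffle_permutation(c: int, groups: int) -> np.ndarray:
    """Channel order produced by a group-interleave shuffle.

    With groups=2 and channels [a, b, c, d] the output order is [a, c, b, d]:
    channel i of group g moves to position i*groups + g.
    """
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    return np.arange(c).reshape(groups, c // groups).T.ravel()


def channel_shuffle(X: np.ndarray, groups: int) -> np.ndarray:
    """Reorder the channel axis (last axis of an H x W x C map) by the
    group-interleave permutation; spatial content untouched."""
    return np.ascontiguousarray(X[..., shuffle_permutation(X.shape[-1], groups)])


class GSConv(nn.Module):
    """Dense branch c1 -> c2/2 (k x k, stride s), depthwise dw_kernel branch on
    those c2/2 channels, concat to c2, then channel shuffle (2 groups).  Both
    branches are conv + BN + SiLU."""

    def __init__(self, cfg: GSConvConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        half = cfg.c2 // 2
        self.dense = nn.Conv2d(cfg.c1, half, cfg.k, cfg.s, bias=False)
        self.bn1 = nn.BatchNorm2d(half)
        self.dw = nn.Conv2d(half, half, cfg.dw_kernel, 1, groups=half, bias=False)
        self.bn2 = nn.BatchNorm2d(half)
        perm = shuffle_permutation(cfg.c2, 2)
        self.perm = perm  # constant indexing, no gradient surprises

    def forward(self, x: Tensor) -> Tensor:
        a = self.bn1(self.dense(x)).silu()
        b = self.bn2(self.dw(a)).silu()
        y = cat([a, b], axis=1)
        return y[:, self.perm]
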
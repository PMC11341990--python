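"""YOLOv7 building blocks: CBS, ELAN, MP transitions, SPPCSPC, RepConv and
the anchor heads, plus the drop-in module variants (ELAN-GS, BiFormer insert).

Channel layout follows the standard single-scale YOLOv7; every variant block
preserves its baseline counterpart's interface shapes so modules can be
swapped without touching the surrounding graph.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, cat
from .bra import BRAConfig, BiFormerBlock
from .gsconv import GSConv, GSConvConfig

__all__ = [
    "ConvBnAct", "ELAN", "NeckELAN", "MPDown", "SPPCSPC", "RepConv",
    "Detect", "BiFormerInsert",
]


class ConvBnAct(nn.Module):
    """CBS block: convolution + batch norm + SiLU."""

    def __init__(self, c1, c2, k=1, s=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


def _branch(c1, c2, k, s, gs: bool, dw_kernel: int):
    if gs:
        return GSConv(GSConvConfig(c1, c2, k, s, dw_kernel))
    return ConvBnAct(c1, c2, k, s)


class ELAN(nn.Module):
    """Efficient layer aggregation block (backbone form).

    Two 1x1 stems; a chain of four 3x3 convolutions off the second stem; the
    concat takes [chain4, chain2, stem2, stem1] and a 1x1 fuses to ``c_out``.
    """

    def __init__(self, c_in, c_hidden, c_branch, c_out):
        super().__init__()
        self.cv1 = ConvBnAct(c_in, c_hidden, 1)
        self.cv2 = ConvBnAct(c_in, c_hidden, 1)
        self.chain = [
            ConvBnAct(c_hidden, c_branch, 3),
            ConvBnAct(c_branch, c_branch, 3),
            ConvBnAct(c_branch, c_branch, 3),
            ConvBnAct(c_branch, c_branch, 3),
        ]
        self.out = ConvBnAct(2 * c_hidden + 2 * c_branch, c_out, 1)

    def forward(self, x):
        y1, y2 = self.cv1(x), self.cv2(x)
        c1 = self.chain[0](y2)
        c2 = self.chain[1](c1)
        c3 = self.chain[2](c2)
        c4 = self.chain[3](c3)
        return self.out(cat([c4, c2, y2, y1], axis=1))


class NeckELAN(nn.Module):
    """Neck aggregation block: same stems and chain, but all six branches feed
    the concat.  With ``gs=True`` the four chain convolutions are GSConv
    (the ELAN-GS block)."""

    def __init__(self, c_in, c_hidden, c_branch, c_out, gs=False, dw_kernel=3):
        super().__init__()
        self.cv1 = ConvBnAct(c_in, c_hidden, 1)
        self.cv2 = ConvBnAct(c_in, c_hidden, 1)
        self.chain = [
            _branch(c_hidden, c_branch, 3, 1, gs, dw_kernel),
            _branch(c_branch, c_branch, 3, 1, gs, dw_kernel),
            _branch(c_branch, c_branch, 3, 1, gs, dw_kernel),
            _branch(c_branch, c_branch, 3, 1, gs, dw_kernel),
        ]
        self.out = ConvBnAct(2 * c_hidden + 4 * c_branch, c_out, 1)

    def forward(self, x):
        y1, y2 = self.cv1(x), self.cv2(x)
        c1 = self.chain[0](y2)
        c2 = self.chain[1](c1)
        c3 = self.chain[2](c2)
        c4 = self.chain[3](c3)
        return self.out(cat([c4, c3, c2, c1, y2, y1], axis=1))


class MPDown(nn.Module):
    """Max-pool transition: a pooled 1x1 branch and a strided 3x3 branch,
    concatenated (each at ``c_branch`` channels)."""

    def __init__(self, c_in, c_branch, gs=False, dw_kernel=3):
        super().__init__()
        self.pool = nn.MaxPool2d(2, 2)
        self.cv1 = ConvBnAct(c_in, c_branch, 1)
        self.cv2 = ConvBnAct(c_in, c_branch, 1)
        self.cv3 = _branch(c_branch, c_branch, 3, 2, gs, dw_kernel)

    def forward(self, x):
        a = self.cv1(self.pool(x))
        b = self.cv3(self.cv2(x))
        return cat([b, a], axis=1)


class SPPCSPC(nn.Module):
    """Spatial-pyramid-pooling CSP block (pool sizes 5/9/13)."""

    def __init__(self, c1, c2):
        super().__init__()
        c_ = c2
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c1, c_, 1)
        self.cv3 = ConvBnAct(c_, c_, 3)
        self.cv4 = ConvBnAct(c_, c_, 1)
        self.pools = [nn.MaxPool2d(k, 1, k // 2) for k in (5, 9, 13)]
        self.cv5 = ConvBnAct(4 * c_, c_, 1)
        self.cv6 = ConvBnAct(c_, c_, 3)
        self.cv7 = ConvBnAct(2 * c_, c2, 1)

    def forward(self, x):
        x1 = self.cv4(self.cv3(self.cv1(x)))
        y1 = self.cv6(self.cv5(cat([x1] + [p(x1) for p in self.pools], axis=1)))
        return self.cv7(cat([y1, self.cv2(x)], axis=1))


class RepConv(nn.Module):
    """Re-parameterizable conv: parallel 3x3 and 1x1 conv+BN branches at train
    time; they fold into a single biased 3x3 at deployment."""

    def __init__(self, c1, c2, s=1):
        super().__init__()
        self.c1, self.c2, self.s = c1, c2, s
        self.dense = nn.Conv2d(c1, c2, 3, s, bias=False)
        self.bn_dense = nn.BatchNorm2d(c2)
        self.one = nn.Conv2d(c1, c2, 1, s, p=0, bias=False)
        self.bn_one = nn.BatchNorm2d(c2)
        self.deploy = False

    def fuse_weights(self):
        """Merge both conv+BN branches into one biased 3x3 kernel."""
        def scale_shift(bn):
            s = bn.weight.data / np.sqrt(bn.running_var + bn.eps)
            return s, bn.bias.data - bn.running_mean * s

        s3, b3 = scale_shift(self.bn_dense)
        s1, b1 = scale_shift(self.bn_one)
        w = self.dense.weight.data * s3[:, None, None, None]
        w1 = self.one.weight.data * s1[:, None, None, None]
        w = w.copy()
        w[:, :, 1:2, 1:2] += w1
        return w, b3 + b1

    def forward(self, x):
        if self.deploy and not self.training:
            w, b = self.fuse_weights()
            return x.conv2d(Tensor(w), Tensor(b), stride=self.s, padding=1).silu()
        return (self.bn_dense(self.dense(x)) + self.bn_one(self.one(x))).silu()


class Detect(nn.Module):
    """Anchor heads with implicit add/multiply knowledge, one 1x1 conv per
    scale emitting 3 * (5 + num_classes) channels."""

    def __init__(self, channels, num_classes, anchors, strides, input_size=640):
        super().__init__()
        self.nc = num_classes
        self.no = 5 + num_classes
        self.na = len(anchors[0])
        self.anchors = np.asarray(anchors, dtype=np.float32)  # (3, 3, 2) pixels
        self.strides = np.asarray(strides, dtype=np.float32)
        self.convs = [nn.Conv2d(c, self.na * self.no, 1, bias=True) for c in channels]
        # prior bias init: start objectness at the expected object density and
        # class probabilities near the single-class prior, so early training
        # does not spend itself suppressing background
        for conv, s in zip(self.convs, strides):
            b = conv.bias.data.reshape(self.na, self.no)
            b[:, 4] = np.log(8 / (input_size / s) ** 2)
            b[:, 5:] = np.log(0.6 / (num_classes - 0.99999))
        self.ia = [nn.Parameter(np.zeros((1, c, 1, 1), dtype=np.float32))
                   for c in channels]
        self.im = [nn.Parameter(np.ones((1, self.na * self.no, 1, 1), dtype=np.float32))
                   for c in channels]

    def forward(self, feats):
        return [conv(f + ia) * im
                for conv, ia, im, f in zip(self.convs, self.ia, self.im, feats)]


class BiFormerInsert(nn.Module):
    """BiFormer block behind a 1x1 channel bottleneck, appended after a
    backbone ELAN stage.  The embedding width sets the parameter budget of
    the insertion."""

    def __init__(self, c: int, embed: int, cfg: BRAConfig, mlp_ratio: int = 3):
        super().__init__()
        self.reduce = ConvBnAct(c, embed, 1)
        self.block = BiFormerBlock(embed, cfg, mlp_ratio)
        self.expand = ConvBnAct(embed, c, 1)

    def forward(self, x):
        return self.expand(self.block(self.reduce(x)))
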
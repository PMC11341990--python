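"""Bi-level routing attention (BRA) and the BiFormer block built on it.

BRA makes self-attention sparse in two stages.  A feature map ``X`` (H x W x C)
is split into ``S x S`` non-overlapping regions; region-mean queries and keys
``Qr, Kr`` form an affinity matrix ``Ar = Qr Kr^T`` whose row-wise top-k column
indices ``Ir`` select, for every region, the k regions it is allowed to attend
to.  Keys and values of the routed regions are gathered, and ordinary scaled
dot-product attention then runs token-to-token *within* each region's gathered
set.  A depthwise 5x5 "local context enhancement" convolution of the value map
is added to the attention output, so purely local structure survives even when
routing is very sparse.

Two surfaces are provided:

* a functional numpy API (``region_routing``, ``gather_kv``, ``lce``,
  ``bra_attention``) on single H x W x C maps, exposing every intermediate for
  inspection and testing;
* autodiff modules (:class:`BiLevelRoutingAttention`, :class:`BiFormerBlock`)
  on batched NCHW tensors, used inside the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "BRAConfig", "ProjectionWeights", "BRAParams", "RoutingState",
    "region_routing", "gather_kv", "lce", "bra_attention",
    "BiLevelRoutingAttention", "BiFormerBlock",
]


# --------------------------------------------------------------------------
# configuration and state containers
# --------------------------------------------------------------------------

@dataclass
class BRAConfig:
    """Routing-attention hyperparameters.

    S
        regions per image side; the affinity matrix is S^2 x S^2.
    topk
        routed regions kept per region, 1 <= topk <= S^2.
    num_heads
        attention heads; the embedding must divide evenly.
    lce_kernel
        odd kernel of the depthwise local-context convolution (default 5).
    pad_to_fit
        zero-pad H, W up to multiples of S (output cropped back) instead of
        rejecting non-divisible inputs.
    """

    S: int = 8
    topk: int = 4
    num_heads: int = 1
    lce_kernel: int = 5
    pad_to_fit: bool = True

    def validate(self, embed_dim: int | None = None):
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not 1 <= self.topk <= self.S**2:
            raise ValueError(f"topk={self.topk} outside [1, S^2={self.S ** 2}]")
        if self.lce_kernel % 2 == 0:
            raise ValueError("lce_kernel must be odd")
        if embed_dim is not None and embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")


@dataclass
class ProjectionWeights:
    """Square query/key/value projections (C x C each)."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray


@dataclass
class BRAParams:
    proj: ProjectionWeights
    Wo: np.ndarray                       # output projection C x C
    lce_kernel: np.ndarray               # depthwise weights C x k x k


@dataclass
class RoutingState:
    """Intermediates of the coarse routing stage (regions x tokens x C)."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    Qr: np.ndarray
    Kr: np.ndarray
    Ar: np.ndarray
    Ir: np.ndarray
    region_hw: tuple = field(default=(0, 0))


# --------------------------------------------------------------------------
# functional API (numpy, single map)
# --------------------------------------------------------------------------

def _to_regions(x: np.ndarray, S: int) -> np.ndarray:
    """(H, W, C) -> (S^2, tokens_per_region, C), regions row-major."""
    h, w, c = x.shape
    rh, rw = h // S, w // S
    x = x.reshape(S, rh, S, rw, c).transpose(0, 2, 1, 3, 4)
    return x.reshape(S * S, rh * rw, c)


def _pad_map(x: np.ndarray, S: int, allow_pad: bool) -> np.ndarray:
    h, w, _ = x.shape
    if h % S == 0 and w % S == 0:
        return x
    if not allow_pad:
        raise ValueError(f"spatial dims {h}x{w} not divisible by S={S}")
    ph, pw = (-h) % S, (-w) % S
    return np.pad(x, ((0, ph), (0, pw), (0, 0)))


def region_routing(X: np.ndarray, weights: ProjectionWeights,
                   cfg: BRAConfig) -> RoutingState:
    """Project to Q/K/V, pool per region and route: Ar = Qr Kr^T, Ir = top-k.

    Rows of ``Ir`` list the ``topk`` most affine regions in descending
    affinity; ties break toward the lower region index.
    """
    cfg.validate()
    X = _pad_map(np.asarray(X, dtype=np.float64), cfg.S, cfg.pad_to_fit)
    xr = _to_regions(X, cfg.S)
    q, k, v = xr @ weights.Wq, xr @ weights.Wk, xr @ weights.Wv
    qr, kr = q.mean(axis=1), k.mean(axis=1)
    ar = qr @ kr.T
    ir = np.argsort(-ar, axis=1, kind="stable")[:, : cfg.topk]
    rh, rw = X.shape[0] // cfg.S, X.shape[1] // cfg.S
    return RoutingState(q, k, v, qr, kr, ar, ir, (rh, rw))


def gather_kv(K: np.ndarray, V: np.ndarray, Ir: np.ndarray,
              cfg: BRAConfig) -> tuple[np.ndarray, np.ndarray]:
    """Collect the K/V tokens of each region's routed regions, in Ir order."""
    n_regions = K.shape[0]
    if Ir.min() < 0 or Ir.max() >= n_regions:
        raise IndexError("routing index out of range")
    s2, n, c = K.shape
    kg = K[Ir].reshape(s2, Ir.shape[1] * n, c)
    vg = V[Ir].reshape(s2, Ir.shape[1] * n, c)
    return kg, vg


def lce(V: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Depthwise same-padded convolution of the value map (local context).

    ``kernel`` has shape (C, k, k): one k x k filter per channel, channels
    never mix.  Zero padding at the border.
    """
    k = kernel.shape[-1]
    if k % 2 == 0:
        raise ValueError("LCE kernel must be odd")
    h, w, c = V.shape
    if kernel.shape[0] != c:
        raise ValueError("kernel/channel mismatch")
    pad = k // 2
    vp = np.pad(V, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros_like(V, dtype=np.float64)
    for i in range(k):
        for j in range(k):
            out += vp[i:i + h, j:j + w] * kernel[:, i, j]
    return out


def bra_attention(X: np.ndarray, cfg: BRAConfig, params: BRAParams) -> np.ndarray:
    """Full BRA operator: O = Wo(Attention(Q, Kg, Vg)) + LCE(V).

    Attention is scaled-dot-product softmax per query token over only the
    gathered tokens of its region's routed set; logits are scaled by
    1/sqrt(head_dim).  Output has the same H x W x C shape as the input.
    """
    h, w, c = X.shape
    cfg.validate(embed_dim=c)
    state = region_routing(X, params.proj, cfg)
    kg, vg = gather_kv(state.K, state.V, state.Ir, cfg)
    s2, n, _ = state.Q.shape
    nh, hd = cfg.num_heads, c // cfg.num_heads
    # (S^2, heads, tokens, head_dim)
    q = state.Q.reshape(s2, n, nh, hd).transpose(0, 2, 1, 3)
    kgh = kg.reshape(s2, -1, nh, hd).transpose(0, 2, 1, 3)
    vgh = vg.reshape(s2, -1, nh, hd).transpose(0, 2, 1, 3)
    logits = q @ kgh.transpose(0, 1, 3, 2) / np.sqrt(hd)
    logits -= logits.max(axis=-1, keepdims=True)
    attn = np.exp(logits)
    attn /= attn.sum(axis=-1, keepdims=True)
    out = (attn @ vgh).transpose(0, 2, 1, 3).reshape(s2, n, c)
    out = out @ params.Wo
    # back to (padded) map, add local context, crop padding
    S, (rh, rw) = cfg.S, state.region_hw
    out_map = out.reshape(S, S, rh, rw, c).transpose(0, 2, 1, 3, 4).reshape(
        S * rh, S * rw, c
    )
    v_map = state.V.reshape(S, S, rh, rw, c).transpose(0, 2, 1, 3, 4).reshape(
        S * rh, S * rw, c
    )
    out_map = out_map + lce(v_map, params.lce_kernel)
    return out_map[:h, :w]


# --------------------------------------------------------------------------
# autodiff modules (batched NCHW)
# --------------------------------------------------------------------------

class BiLevelRoutingAttention(nn.Module):
    """Batched BRA on NCHW tensors; the routing indices are not differentiated
    (they are a discrete selection), everything else is."""

    def __init__(self, dim: int, cfg: BRAConfig):
        super().__init__()
        cfg.validate(embed_dim=dim)
        self.dim, self.cfg = dim, cfg
        self.wq = nn.Linear(dim, dim, bias=False)
        self.wk = nn.Linear(dim, dim, bias=False)
        self.wv = nn.Linear(dim, dim, bias=False)
        self.wo = nn.Linear(dim, dim, bias=True)
        self.lce_conv = nn.Conv2d(dim, dim, cfg.lce_kernel, groups=dim, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        S, topk = self.cfg.S, self.cfg.topk
        ph, pw = (-h) % S, (-w) % S
        if ph or pw:
            if not self.cfg.pad_to_fit:
                raise ValueError(f"spatial dims {h}x{w} not divisible by S={S}")
            xp = Tensor._make(
                np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw))), (x,),
                lambda g: x._accumulate(g[:, :, :h, :w]),
            )
        else:
            xp = x
        hp, wp = h + ph, w + pw
        rh, rw = hp // S, wp // S
        n = rh * rw
        # tokens grouped by region: (B, S^2, n, C)
        t = xp.reshape(b, c, S, rh, S, rw).transpose(0, 2, 4, 3, 5, 1)
        t = t.reshape(b, S * S, n, c)
        q, k, v = self.wq(t), self.wk(t), self.wv(t)
        qr, kr = q.mean(axis=2), k.mean(axis=2)          # (B, S^2, C)
        ar = qr @ kr.transpose(0, 2, 1)                   # (B, S^2, S^2)
        ir = np.argsort(-ar.data, axis=2, kind="stable")[:, :, :topk]
        bidx = np.arange(b)[:, None, None]
        kg = k[bidx, ir].reshape(b, S * S, topk * n, c)
        vg = v[bidx, ir].reshape(b, S * S, topk * n, c)
        nh = self.cfg.num_heads
        hd = c // nh
        qh = q.reshape(b, S * S, n, nh, hd).transpose(0, 1, 3, 2, 4)
        kh = kg.reshape(b, S * S, topk * n, nh, hd).transpose(0, 1, 3, 2, 4)
        vh = vg.reshape(b, S * S, topk * n, nh, hd).transpose(0, 1, 3, 2, 4)
        logits = (qh @ kh.transpose(0, 1, 2, 4, 3)) * (1.0 / np.sqrt(hd))
        attn = logits.softmax(axis=-1)
        out = (attn @ vh).transpose(0, 1, 3, 2, 4).reshape(b, S * S, n, c)
        out = self.wo(out)
        # regions back to map
        out = out.reshape(b, S, S, rh, rw, c).transpose(0, 5, 1, 3, 2, 4)
        out = out.reshape(b, c, hp, wp)
        v_map = v.reshape(b, S, S, rh, rw, c).transpose(0, 5, 1, 3, 2, 4)
        v_map = v_map.reshape(b, c, hp, wp)
        out = out + self.lce_conv(v_map)
        if ph or pw:
            out = out[:, :, :h, :w]
        return out


class _TokenMLP(nn.Module):
    def __init__(self, dim: int, ratio: int = 3):
        super().__init__()
        self.fc1 = nn.Linear(dim, ratio * dim)
        self.fc2 = nn.Linear(ratio * dim, dim)

    def forward(self, x):
        return self.fc2(self.fc1(x).silu())


class BiFormerBlock(nn.Module):
    """Residual transformer block: depthwise 3x3 positional conv, then
    LN -> BRA and LN -> MLP, each with a residual connection."""

    def __init__(self, dim: int, cfg: BRAConfig, mlp_ratio: int = 3):
        super().__init__()
        self.pos_conv = nn.Conv2d(dim, dim, 3, groups=dim, bias=True)
        self.norm1 = nn.LayerNorm(dim)
        self.attn = BiLevelRoutingAttention(dim, cfg)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = _TokenMLP(dim, mlp_ratio)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.pos_conv(x)
        b, c, h, w = x.shape
        t = x.transpose(0, 2, 3, 1)                      # (B,H,W,C) tokens
        n1 = self.norm1(t).transpose(0, 3, 1, 2)
        x = x + self.attn(n1)
        t = x.transpose(0, 2, 3, 1)
        x = x + self.mlp(self.norm2(t)).transpose(0, 3, 1, 2)
        return x
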
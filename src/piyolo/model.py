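"""Detector assembly, variants, profiling and inference.

The baseline is the standard single-scale YOLOv7: a CBS stem, four ELAN
stages with max-pool transitions (P3/P4/P5 taps at strides 8/16/32), an
SPPCSPC + PAFPN neck with two upsample sites, and RepConv heads.  Three
independently switchable modules define the PI-YOLO variants:

* ``use_biformer`` — a bottlenecked BiFormer block after the last two
  backbone ELAN stages;
* ``use_carafe``   — CARAFE upsamplers in place of nearest-neighbor at the
  two neck upsample sites;
* ``use_gsconv``   — ELAN-GS neck blocks (four GSConv chain convs) and GSConv
  strided downsamplers in the neck transitions.

Profiling reports the *deployment* graph — RepConv branches merged, batch
norm folded into conv biases, implicit knowledge folded — which is the form
in which such detectors are benchmarked; compute is measured by counting the
multiply-accumulates actually executed in one forward pass, times two.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .bra import BRAConfig
from .carafe import CARAFE, CarafeConfig
from .gsconv import GSConv
from .blocks import (
    BiFormerInsert, ConvBnAct, Detect, ELAN, MPDown, NeckELAN, RepConv, SPPCSPC,
)
from .metrics import box_iou_matrix

__all__ = [
    "ModelConfig", "DetectionSet", "Detector", "VARIANTS", "variant_config",
    "build_model", "profile_model", "detect", "nms",
    "save_checkpoint", "load_checkpoint",
]

# COCO anchor priors of the YOLO family, pixels at 640 input.
DEFAULT_ANCHORS = (
    ((12, 16), (19, 36), (40, 28)),       # stride 8
    ((36, 75), (76, 55), (72, 146)),      # stride 16
    ((142, 110), (192, 243), (459, 401)),  # stride 32
)


@dataclass
class ModelConfig:
    use_biformer: bool = False
    use_carafe: bool = False
    use_gsconv: bool = False
    num_classes: int = 1
    input_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    width_multiple: float = 1.0
    # module hyperparameters (widths calibrated against the ablation table)
    biformer_embed: int = 88
    biformer_S: tuple = (8, 4)
    biformer_topk: int = 4
    biformer_heads: int = 4
    carafe_cm: int = 108
    gs_dw_kernel: int = 3
    conf_thr: float = 0.25
    iou_thr: float = 0.45

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if any(a <= 0 for scale in self.anchors for wh in scale for a in wh):
            raise ValueError("anchors must be positive")


VARIANTS = {
    "yolov7": dict(),
    "yolov7-biformer": dict(use_biformer=True),
    "yolov7-carafe": dict(use_carafe=True),
    "yolov7-gsconv": dict(use_gsconv=True),
    "pi-yolo": dict(use_biformer=True, use_carafe=True, use_gsconv=True),
}


def variant_config(name: str, **overrides) -> ModelConfig:
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    return ModelConfig(**{**VARIANTS[name], **overrides})


def _make_divisible(x: float, d: int) -> int:
    return max(d, int(np.ceil(x / d) * d))


@dataclass
class DetectionSet:
    """Predicted boxes (x1, y1, x2, y2 pixels), confidences and class labels."""

    boxes: np.ndarray
    scores: np.ndarray
    classes: np.ndarray

    def __len__(self):
        return len(self.boxes)


class Detector(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        wm = cfg.width_multiple
        ch = lambda c: _make_divisible(c * wm, 8) if wm != 1.0 else c
        gs, dwk = cfg.use_gsconv, cfg.gs_dw_kernel
        c32, c64, c128 = ch(32), ch(64), ch(128)
        c256, c512, c1024 = ch(256), ch(512), ch(1024)

        # ---- backbone (concat widths derived, so any rounding stays
        # ---- interface-consistent) ---------------------------------------
        self.stem = [
            ConvBnAct(3, c32, 3), ConvBnAct(c32, c64, 3, 2),
            ConvBnAct(c64, c64, 3), ConvBnAct(c64, c128, 3, 2),
        ]
        self.elan1 = ELAN(c128, c64, c64, c256)
        self.down2 = MPDown(c256, c128)
        self.elan2 = ELAN(2 * c128, c128, c128, c512)      # P3 tap
        self.down3 = MPDown(c512, c256)
        self.elan3 = ELAN(2 * c256, c256, c256, c1024)     # P4 tap
        self.down4 = MPDown(c1024, c512)
        self.elan4 = ELAN(2 * c512, c256, c256, c1024)     # P5 tap
        if cfg.use_biformer:
            heads = cfg.biformer_heads
            embed = _make_divisible(cfg.biformer_embed * wm, heads) \
                if wm != 1.0 else cfg.biformer_embed
            s16, s32 = cfg.biformer_S
            self.bif3 = BiFormerInsert(
                c1024, embed, BRAConfig(s16, cfg.biformer_topk, heads))
            self.bif4 = BiFormerInsert(
                c1024, embed, BRAConfig(s32, cfg.biformer_topk, heads))

        # ---- neck (SPPCSPC + PAFPN) --------------------------------------
        self.spp = SPPCSPC(c1024, c512)
        self.up1_conv = ConvBnAct(c512, c256, 1)
        self.route_p4 = ConvBnAct(c1024, c256, 1)
        self.up2_conv = ConvBnAct(c256, c128, 1)
        self.route_p3 = ConvBnAct(c512, c128, 1)
        if cfg.use_carafe:
            self.up1 = CARAFE(c256, CarafeConfig(Cm=min(cfg.carafe_cm, c256)))
            self.up2 = CARAFE(c128, CarafeConfig(Cm=min(cfg.carafe_cm, c128)))
        else:
            self.up1 = nn.Upsample(2)
            self.up2 = nn.Upsample(2)
        self.head_elan1 = NeckELAN(2 * c256, c256, c128, c256, gs, dwk)
        self.head_elan2 = NeckELAN(2 * c128, c128, c64, c128, gs, dwk)
        self.down_h1 = MPDown(c128, c128, gs, dwk)
        self.head_elan3 = NeckELAN(2 * c128 + c256, c256, c128, c256, gs, dwk)
        self.down_h2 = MPDown(c256, c256, gs, dwk)
        self.head_elan4 = NeckELAN(2 * c256 + c512, c512, c256, c512, gs, dwk)

        # ---- prediction ---------------------------------------------------
        self.rep1 = RepConv(c128, c256)
        self.rep2 = RepConv(c256, c512)
        self.rep3 = RepConv(c512, c1024)
        self.detect = Detect(
            (c256, c512, c1024), cfg.num_classes, cfg.anchors, (8, 16, 32),
            input_size=cfg.input_size,
        )

    def backbone(self, x):
        for m in self.stem:
            x = m(x)
        x = self.elan1(x)
        p3 = self.elan2(self.down2(x))
        p4 = self.elan3(self.down3(p3))
        p5 = self.elan4(self.down4(p4))
        if self.cfg.use_biformer:
            p4 = self.bif3(p4)
            p5 = self.bif4(p5)
        return p3, p4, p5

    def forward(self, x):
        p3, p4, p5 = self.backbone(x)
        spp = self.spp(p5)
        t1 = self.up1(self.up1_conv(spp))
        f4 = self.head_elan1(nn.cat([self.route_p4(p4), t1], axis=1))
        t2 = self.up2(self.up2_conv(f4))
        f3 = self.head_elan2(nn.cat([self.route_p3(p3), t2], axis=1))
        d3 = self.head_elan3(nn.cat([self.down_h1(f3), f4], axis=1))
        d5 = self.head_elan4(nn.cat([self.down_h2(d3), spp], axis=1))
        return self.detect([self.rep1(f3), self.rep2(d3), self.rep3(d5)])


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    """Construct a detector with reproducible initialisation."""
    nn.seed_all(seed)
    return Detector(cfg)


# --------------------------------------------------------------------------
# profiling
# --------------------------------------------------------------------------

def _deploy_params(m: nn.Module) -> int:
    """Parameter count of the fused deployment graph."""
    if isinstance(m, ConvBnAct):
        return m.conv.weight.size + m.conv.c2            # BN folds into a bias
    if isinstance(m, GSConv):
        return (m.dense.weight.size + m.dense.c2
                + m.dw.weight.size + m.dw.c2)
    if isinstance(m, RepConv):
        return m.c1 * m.c2 * 9 + m.c2                    # merged 3x3 + bias
    if isinstance(m, Detect):
        return sum(c.weight.size + c.bias.size for c in m.convs)
    total = sum(_deploy_params(c) for c in m._children())
    # leaves that survive deployment as-is
    if isinstance(m, (nn.Conv2d, nn.Linear)):
        total += m.weight.size + (m.bias.size if m.bias is not None else 0)
    elif isinstance(m, nn.LayerNorm):
        total += m.weight.size + m.bias.size
    return total


def profile_model(model: Detector, input_size: int | None = None):
    """(params in M, GFLOPs) of the deployment graph at ``input_size``.

    Parameters are counted from the model's arrays after notional fusion;
    compute is the multiply-accumulates executed by one forward pass on a
    single image, counted as two floating-point operations each.
    """
    size = input_size or model.cfg.input_size
    params = _deploy_params(model)
    was_training = model.training
    model.eval()
    reps = [m for m in model.modules() if isinstance(m, RepConv)]
    for r in reps:
        r.deploy = True
    x = nn.Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    with nn.no_grad(), nn.count_macs() as mc:
        model(x)
    for r in reps:
        r.deploy = False
    model.train(was_training)
    return round(params / 1e6, 2), round(mc.total / 1e9, 2)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def decode_predictions(model: Detector, raw: list, conf_thr: float):
    """Raw head maps -> (boxes xyxy, scores, classes) in network pixels."""
    det = model.detect
    boxes, scores, classes = [], [], []
    for si, p in enumerate(raw):
        stride = det.strides[si]
        b, _, h, w = p.shape
        assert b == 1
        p = p.data.reshape(det.na, det.no, h, w)
        p = 1.0 / (1.0 + np.exp(-p))
        gy, gx = np.mgrid[0:h, 0:w]
        xy = np.stack([(2 * p[:, 0] - 0.5 + gx), (2 * p[:, 1] - 0.5 + gy)],
                      axis=-1) * stride
        anc = det.anchors[si].reshape(det.na, 1, 1, 2)
        wh = (2 * p[:, 2:4].transpose(0, 2, 3, 1)) ** 2 * anc
        conf = p[:, 4][..., None] * p[:, 5:5 + det.nc].transpose(0, 2, 3, 1)
        cls = conf.argmax(axis=-1)
        score = conf.max(axis=-1)
        keep = score > conf_thr
        if not keep.any():
            continue
        xy, wh = xy[keep], wh[keep]
        boxes.append(np.concatenate([xy - wh / 2, xy + wh / 2], axis=-1))
        scores.append(score[keep])
        classes.append(cls[keep])
    if not boxes:
        z = np.zeros
        return z((0, 4), np.float32), z(0, np.float32), z(0, np.int64)
    return (np.concatenate(boxes), np.concatenate(scores),
            np.concatenate(classes))


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-ordered."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = box_iou_matrix(boxes[i:i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thr]
    return np.asarray(keep, dtype=np.int64)


def detect(model: Detector, image: np.ndarray, conf_thr: float | None = None,
           iou_thr: float | None = None) -> DetectionSet:
    """Run the detector on one H x W x 3 uint8 image.

    The image is letterboxed to the configured input size; boxes are decoded,
    confidence-filtered, class-wise NMS-suppressed, mapped back to original
    image coordinates and clipped.
    """
    from .data import letterbox

    cfg = model.cfg
    conf_thr = cfg.conf_thr if conf_thr is None else conf_thr
    iou_thr = cfg.iou_thr if iou_thr is None else iou_thr
    h0, w0 = image.shape[:2]
    canvas, scale, (px, py) = letterbox(image, cfg.input_size)
    x = nn.Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    was_training = model.training
    model.eval()
    with nn.no_grad():
        raw = model(x)
    model.train(was_training)
    boxes, scores, classes = decode_predictions(model, raw, conf_thr)
    kept_b, kept_s, kept_c = [], [], []
    for c in np.unique(classes):
        m = classes == c
        k = nms(boxes[m], scores[m], iou_thr)
        kept_b.append(boxes[m][k])
        kept_s.append(scores[m][k])
        kept_c.append(np.full(len(k), c, dtype=np.int64))
    if kept_b:
        boxes = np.concatenate(kept_b)
        scores = np.concatenate(kept_s)
        classes = np.concatenate(kept_c)
    boxes[:, [0, 2]] = np.clip((boxes[:, [0, 2]] - px) / scale, 0, w0)
    boxes[:, [1, 3]] = np.clip((boxes[:, [1, 3]] - py) / scale, 0, h0)
    ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
    order = np.argsort(-scores[ok], kind="stable")
    return DetectionSet(boxes[ok][order], scores[ok][order], classes[ok][order])


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: Detector, path):
    sd = model.state_dict()
    cfg = asdict(model.cfg)
    np.savez_compressed(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **sd)


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        cfg_raw = bytes(z["__config__"]).decode()
        cfg_d = json.loads(cfg_raw)
        cfg_d["anchors"] = tuple(tuple(tuple(a) for a in s) for s in cfg_d["anchors"])
        cfg_d["biformer_S"] = tuple(cfg_d["biformer_S"])
        model = Detector(ModelConfig(**cfg_d))
        sd = {k: z[k] for k in z.files if k != "__config__"}
    model.load_state_dict(sd)
    return model
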
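"""Composite detection loss: CIoU box regression, objectness BCE, class BCE.

Targets are assigned YOLO-style: a ground-truth box is matched to every
anchor whose width/height ratio to the box is within a factor of 4, at the
box's grid cell and its two nearest neighbor cells, on every scale where the
gate passes.  The objectness target at an assigned location is the detached
CIoU of the current prediction, so the confidence head learns to score
localisation quality.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

__all__ = ["build_targets", "ciou", "compute_loss"]

LAMBDA_BOX, LAMBDA_OBJ, LAMBDA_CLS = 0.05, 0.7, 0.3
OBJ_BALANCE = (4.0, 1.0, 0.4)          # stride 8 / 16 / 32
ANCHOR_T = 4.0                          # anchor-ratio gate


def build_targets(det, batch_boxes: list, img_size: int, grids: list):
    """Per-scale assignment of normalised GT boxes.

    Returns, for each scale, a dict of index arrays (image, anchor, gy, gx)
    and target arrays (txy in-cell offset target, twh in grid units, wh of
    the matched anchor in grid units, cls).
    """
    out = []
    for si, (h, w) in enumerate(grids):
        stride = det.strides[si]
        anchors = det.anchors[si] / stride            # grid units
        bi, ai, gj, gi, txy, twh, tcls = [], [], [], [], [], [], []
        for b, boxes in enumerate(batch_boxes):
            for cls, cx, cy, bw, bh in boxes:
                gxy = np.array([cx * w, cy * h])
                gwh = np.array([bw * w, bh * h])
                if gwh.min() <= 0:
                    continue
                for a in range(len(anchors)):
                    r = gwh / anchors[a]
                    if max(r.max(), (1 / r).max()) >= ANCHOR_T:
                        continue
                    cells = [np.floor(gxy)]
                    fx, fy = gxy % 1.0
                    if fx < 0.5 and gxy[0] > 1:
                        cells.append(np.floor(gxy) + [-1, 0])
                    elif fx >= 0.5 and gxy[0] < w - 1:
                        cells.append(np.floor(gxy) + [1, 0])
                    if fy < 0.5 and gxy[1] > 1:
                        cells.append(np.floor(gxy) + [0, -1])
                    elif fy >= 0.5 and gxy[1] < h - 1:
                        cells.append(np.floor(gxy) + [0, 1])
                    for c in cells:
                        x, y = int(c[0]), int(c[1])
                        if not (0 <= x < w and 0 <= y < h):
                            continue
                        bi.append(b); ai.append(a); gj.append(y); gi.append(x)
                        txy.append(gxy - [x, y])
                        twh.append(gwh)
                        tcls.append(int(cls))
        out.append(dict(
            b=np.asarray(bi, int), a=np.asarray(ai, int),
            gj=np.asarray(gj, int), gi=np.asarray(gi, int),
            txy=np.asarray(txy, np.float32).reshape(-1, 2),
            twh=np.asarray(twh, np.float32).reshape(-1, 2),
            anchors=anchors.astype(np.float32),
            cls=np.asarray(tcls, int),
        ))
    return out


def ciou(pxy: Tensor, pwh: Tensor, txy: np.ndarray, twh: np.ndarray) -> Tensor:
    """Complete IoU between predicted and target boxes (centre/size form)."""
    px1, py1 = pxy[:, 0] - pwh[:, 0] * 0.5, pxy[:, 1] - pwh[:, 1] * 0.5
    px2, py2 = pxy[:, 0] + pwh[:, 0] * 0.5, pxy[:, 1] + pwh[:, 1] * 0.5
    tx1, ty1 = txy[:, 0] - twh[:, 0] * 0.5, txy[:, 1] - twh[:, 1] * 0.5
    tx2, ty2 = txy[:, 0] + twh[:, 0] * 0.5, txy[:, 1] + twh[:, 1] * 0.5
    iw = px2.minimum(Tensor(tx2)) - px1.maximum(Tensor(tx1))
    ih = py2.minimum(Tensor(ty2)) - py1.maximum(Tensor(ty1))
    inter = iw.clamp(0) * ih.clamp(0)
    union = pwh[:, 0] * pwh[:, 1] + twh[:, 0] * twh[:, 1] - inter + 1e-7
    iou = inter / union
    # enclosing-box diagonal and centre distance
    cw = px2.maximum(Tensor(tx2)) - px1.minimum(Tensor(tx1))
    chh = py2.maximum(Tensor(ty2)) - py1.minimum(Tensor(ty1))
    c2 = cw * cw + chh * chh + 1e-7
    rho2 = (pxy[:, 0] - txy[:, 0]) ** 2 + (pxy[:, 1] - txy[:, 1]) ** 2
    v = (4 / np.pi**2) * ((Tensor(twh[:, 0] / twh[:, 1]).atan()
                           - (pwh[:, 0] / pwh[:, 1]).atan()) ** 2)
    alpha = (v / ((1 - iou) + v + 1e-7)).detach()
    return iou - rho2 / c2 - alpha * v


def compute_loss(preds: list, batch_boxes: list, det, img_size: int):
    """Total loss and components for one batch of raw head outputs."""
    grids = [(p.shape[2], p.shape[3]) for p in preds]
    assigned = build_targets(det, batch_boxes, img_size, grids)
    nb = preds[0].shape[0]
    loss_box = Tensor(0.0)
    loss_obj = Tensor(0.0)
    loss_cls = Tensor(0.0)
    n_assigned = 0
    for si, (p, t) in enumerate(zip(preds, assigned)):
        b, _, h, w = p.shape
        pr = p.reshape(b, det.na, det.no, h, w)
        obj_target = np.zeros((b, det.na, h, w), dtype=np.float32)
        n = len(t["b"])
        if n:
            n_assigned += n
            ps = pr[t["b"], t["a"], :, t["gj"], t["gi"]]      # (n, no)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(t["anchors"][t["a"]])
            iou_t = ciou(pxy, pwh, t["txy"], t["twh"])
            loss_box = loss_box + (1.0 - iou_t).mean()
            np.maximum.at(obj_target, (t["b"], t["a"], t["gj"], t["gi"]),
                          np.clip(iou_t.data, 0, None))
            # class BCE is trained even with one class so that the decoded
            # confidence (objectness x class) carries no untrained noise
            onehot = np.zeros((n, det.nc), dtype=np.float32)
            onehot[np.arange(n), t["cls"]] = 1.0
            loss_cls = loss_cls + ps[:, 5:].bce_with_logits(onehot).mean()
        pobj = pr[:, :, 4]
        loss_obj = loss_obj + OBJ_BALANCE[si] * pobj.bce_with_logits(obj_target).mean()
    total = LAMBDA_BOX * loss_box + LAMBDA_OBJ * loss_obj + LAMBDA_CLS * loss_cls
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite loss")
    return total, {
        "box": float(loss_box.data), "obj": float(loss_obj.data),
        "cls": float(loss_cls.data), "total": float(total.data),
        "n_assigned": n_assigned,
    }
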
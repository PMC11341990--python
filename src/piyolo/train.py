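"""Training loop and dataset-level evaluation.

Defaults mirror the study protocol: 200 epochs, batch 24, Adam with beta1
0.937 at a maximum learning rate of 1e-3, step decay (x0.1 at 60% and 85%
of the run), training from scratch without pretrained weights, and mosaic
augmentation on the input side.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import nn
from .data import letterbox, mosaic_augment
from .loss import compute_loss
from .metrics import MetricsReport, evaluate_map
from .model import Detector, ModelConfig, build_model, detect

__all__ = ["TrainConfig", "train_model", "evaluate_model"]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 24
    max_lr: float = 0.001
    optimizer: str = "adam"
    momentum: float = 0.937          # Adam beta1
    lr_schedule: str = "step"
    lr_decay_points: tuple = (0.6, 0.85)
    lr_decay_factor: float = 0.1
    mosaic: bool = True
    auto_anchor: bool = True         # k-means anchors from the training set
    max_steps: int | None = None     # cap for small-scale runs
    eval_every: int | None = None    # epochs between validation passes; None
                                     # follows the presence of a val split
    eval_conf_thr: float = 0.001
    eval_iou_match: float = 0.5

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.max_lr <= 0:
            raise ValueError("training hyperparameters must be positive")


def fit_anchors(dataset, input_size: int, n: int = 9, seed: int = 0):
    """K-means anchor priors from the training boxes (autoanchor).

    Box sizes are taken in network pixels after letterboxing; the ``n``
    cluster centres are sorted by area and grouped 3 per scale.  Falls back
    to None (caller keeps its defaults) when there are fewer boxes than
    clusters.
    """
    whs = []
    for s in dataset:
        h0, w0 = s.image.shape[:2]
        scale = min(input_size / h0, input_size / w0)
        for b in s.boxes:
            whs.append([b[3] * w0 * scale, b[4] * h0 * scale])
    whs = np.asarray(whs)
    if len(whs) < n:
        return None
    from scipy.cluster.vq import kmeans2

    centres, _ = kmeans2(whs, n, minit="++", seed=seed)
    centres = centres[np.argsort(centres.prod(axis=1))]
    centres = np.clip(centres, 2.0, None)
    return tuple(tuple((float(w), float(h))
                       for w, h in centres[i * 3:(i + 1) * 3].round(1))
                 for i in range(3))


def _prepare_batch(samples, size, mosaic, rng):
    imgs, boxes = [], []
    for s in samples:
        if mosaic:
            idx = rng.choice(len(samples), 3, replace=len(samples) < 4)
            s = mosaic_augment([s] + [samples[i] for i in idx], rng,
                               out_size=s.image.shape[0])
        canvas, scale, (px, py) = letterbox(s.image, size)
        h0, w0 = s.image.shape[:2]
        b = s.boxes.copy()
        if len(b):
            # normalised source coords -> normalised letterboxed coords
            b[:, 1] = (b[:, 1] * w0 * scale + px) / size
            b[:, 2] = (b[:, 2] * h0 * scale + py) / size
            b[:, 3] = b[:, 3] * w0 * scale / size
            b[:, 4] = b[:, 4] * h0 * scale / size
        imgs.append(canvas.astype(np.float32).transpose(2, 0, 1) / 255.0)
        boxes.append(b)
    return nn.Tensor(np.stack(imgs)), boxes


def evaluate_model(model: Detector, samples: list, conf_thr: float = 0.001,
                   iou_match: float = 0.5) -> MetricsReport:
    """mAP@iou_match of the detector over a list of labelled images."""
    preds = [detect(model, s.image, conf_thr=conf_thr) for s in samples]
    return evaluate_map(preds, samples, iou_match=iou_match)


def train_model(cfg: TrainConfig, model_cfg: ModelConfig, dataset, seed: int = 0,
                val_dataset: list | None = None, log_path=None,
                checkpoint_path=None, verbose: bool = False):
    """Train from scratch on ``dataset`` (list of LabeledImage).

    Returns (model, MetricsReport on the validation set — or the training set
    when none is given —, history list of per-epoch records).  Fully
    deterministic for a fixed seed.
    """
    if not dataset:
        raise ValueError("empty dataset")
    model = build_model(model_cfg, seed=seed)
    if cfg.auto_anchor:
        fitted = fit_anchors(dataset, model_cfg.input_size, seed=seed)
        if fitted is not None:
            model.cfg.anchors = fitted
            model.detect.anchors = np.asarray(fitted, dtype=np.float32)
    rng = np.random.default_rng(seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.max_lr,
                  betas=(cfg.momentum, 0.999))
    size = model_cfg.input_size
    decay_epochs = {int(cfg.epochs * f) for f in cfg.lr_decay_points}
    history, step = [], 0
    best_map, best_state = -1.0, None
    stop = False
    for epoch in range(cfg.epochs):
        if epoch in decay_epochs:
            opt.lr *= cfg.lr_decay_factor
        order = rng.permutation(len(dataset))
        model.train()
        epoch_loss = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [dataset[j] for j in order[i:i + cfg.batch_size]]
            x, boxes = _prepare_batch(batch, size, cfg.mosaic, rng)
            preds = model(x)
            loss, parts = compute_loss(preds, boxes, model.detect, size)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss.append(parts["total"])
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                stop = True
                break
        record = {"epoch": epoch, "step": step, "lr": opt.lr,
                  "loss": float(np.mean(epoch_loss))}
        due = (val_dataset is not None if cfg.eval_every is None
               else (epoch + 1) % cfg.eval_every == 0)
        if stop or epoch == cfg.epochs - 1 or due:
            rep = evaluate_model(model, val_dataset or dataset,
                                 conf_thr=cfg.eval_conf_thr,
                                 iou_match=cfg.eval_iou_match)
            record.update(map=rep.map, precision=rep.precision, recall=rep.recall)
            if rep.map > best_map:
                best_map, best_state = rep.map, model.state_dict()
        history.append(record)
        if verbose:
            print(", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in record.items()))
        if stop:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    final = evaluate_model(model, val_dataset or dataset,
                           conf_thr=cfg.eval_conf_thr,
                           iou_match=cfg.eval_iou_match)
    if log_path:
        with open(log_path, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=sorted({k for r in history for k in r}))
            wr.writeheader()
            wr.writerows(history)
    if checkpoint_path:
        from .model import save_checkpoint
        save_checkpoint(model, checkpoint_path)
    return model, final, history
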
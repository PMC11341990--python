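"""Dataset I/O, mosaic augmentation and the synthetic vessel-patch generator.

Annotations use the YOLO text dialect: one ``class cx cy w h`` line per
object, coordinates normalised to [0, 1].  The synthetic generator emulates
the situation the detector targets — H&E-stained tissue patches in which
ring-shaped blood-vessel cross sections (a lighter lumen inside a darker
wall) of widely varying size sit on a pink, nucleus-speckled background — so
the whole pipeline can be exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

__all__ = [
    "LabeledImage", "parse_label_file", "write_label_file", "load_dataset",
    "letterbox", "hsv_jitter", "mosaic_augment", "generate_synthetic_sample",
    "write_synthetic_dataset",
]


@dataclass
class LabeledImage:
    """Image (H x W x 3 uint8) plus normalised (class, cx, cy, w, h) boxes."""

    image: np.ndarray
    boxes: np.ndarray          # (N, 5) float: class, cx, cy, w, h in [0,1]
    path: str | None = None

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 5)

    def xyxy(self) -> np.ndarray:
        """Boxes in pixel x1, y1, x2, y2."""
        h, w = self.image.shape[:2]
        b = self.boxes
        cx, cy, bw, bh = b[:, 1] * w, b[:, 2] * h, b[:, 3] * w, b[:, 4] * h
        return np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)

    def class_ids(self) -> np.ndarray:
        return self.boxes[:, 0].astype(int)


# --------------------------------------------------------------------------
# label files
# --------------------------------------------------------------------------

class LabelParseError(ValueError):
    pass


def parse_label_file(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(
                    f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise LabelParseError(f"{path}:{ln}: {e}") from None
            if cls < 0 or not all(0.0 <= v <= 1.0 for v in vals):
                raise LabelParseError(
                    f"{path}:{ln}: values outside [0, 1]: {line!r}")
            if vals[2] <= 0 or vals[3] <= 0:
                raise LabelParseError(f"{path}:{ln}: non-positive box size")
            rows.append([cls] + vals)
    return np.asarray(rows, dtype=np.float64).reshape(-1, 5)


def write_label_file(path, boxes: np.ndarray):
    with open(path, "w") as fh:
        for cls, cx, cy, w, h in np.asarray(boxes).reshape(-1, 5):
            fh.write(f"{int(cls)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")


def load_dataset(root, split_ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Deterministic seeded split of an image+label directory.

    Returns (train, val, test) lists of LabeledImage; counts follow the
    ratios with the remainder going to the last split (2000 at 7:2:1 gives
    1400/400/200).
    """
    root = Path(root)
    paths = sorted(p for p in root.iterdir()
                   if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
    if not paths:
        raise FileNotFoundError(f"no images under {root}")
    samples = []
    for p in paths:
        boxes = parse_label_file(p.with_suffix(".txt"))
        img = np.asarray(Image.open(p).convert("RGB"))
        samples.append(LabeledImage(img, boxes, str(p)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n = len(samples)
    n1 = int(round(n * split_ratios[0]))
    n2 = int(round(n * split_ratios[1]))
    idx = [order[:n1], order[n1:n1 + n2], order[n1 + n2:]]
    return tuple([samples[i] for i in part] for part in idx)


# --------------------------------------------------------------------------
# geometric / photometric ops
# --------------------------------------------------------------------------

def letterbox(image: np.ndarray, size: int, fill: int = 114):
    """Aspect-preserving resize onto a size x size gray canvas.

    Returns (canvas, scale, (pad_x, pad_y)) so boxes map back via
    (x - pad_x) / scale.
    """
    h, w = image.shape[:2]
    scale = min(size / h, size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((size, size, 3), fill, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, scale, (px, py)


def hsv_jitter(image: np.ndarray, rng: np.random.Generator,
               gains=(0.015, 0.7, 0.4)) -> np.ndarray:
    """Multiplicative HSV gain jitter (hue wraps, saturation/value clip)."""
    gh, gs, gv = rng.uniform(-1, 1, 3) * gains + 1
    hsv = skcolor.rgb2hsv(image.astype(np.float32) / 255.0)
    hsv[..., 0] = (hsv[..., 0] * gh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * gs, 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * gv, 0, 1)
    out = skcolor.hsv2rgb(hsv)
    return (out * 255.0 + 0.5).astype(np.uint8)


def mosaic_augment(samples: list, rng: np.random.Generator, out_size: int = 512,
                   flip: bool = True, jitter: bool = True,
                   center: tuple | None = None,
                   min_area_frac: float = 0.10) -> LabeledImage:
    """Compose four images into one canvas around a jittered centre.

    Each sample is (optionally) horizontally flipped with p = 0.5 and HSV
    jittered, then anchored at the centre point of its quadrant; whatever
    does not fit is cropped away.  Box coordinates are remapped, clipped to
    the canvas, and dropped when the surviving area falls below
    ``min_area_frac`` of the original box.
    """
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 samples")
    if center is None:
        lo, hi = int(out_size * 0.25), int(out_size * 0.75)
        cx = int(rng.integers(lo, hi + 1))
        cy = int(rng.integers(lo, hi + 1))
    else:
        cx, cy = center
    canvas = np.full((out_size, out_size, 3), 114, dtype=np.uint8)
    out_boxes = []
    for q, s in enumerate(samples):
        img, boxes = s.image, s.boxes.copy()
        h, w = img.shape[:2]
        if flip and rng.random() < 0.5:
            img = img[:, ::-1]
            boxes[:, 1] = 1.0 - boxes[:, 1]
        if jitter:
            img = hsv_jitter(img, rng)
        # quadrant destination rectangle on the canvas
        if q == 0:
            x1d, y1d, x2d, y2d = max(cx - w, 0), max(cy - h, 0), cx, cy
        elif q == 1:
            x1d, y1d, x2d, y2d = cx, max(cy - h, 0), min(cx + w, out_size), cy
        elif q == 2:
            x1d, y1d, x2d, y2d = max(cx - w, 0), cy, cx, min(cy + h, out_size)
        else:
            x1d, y1d, x2d, y2d = cx, cy, min(cx + w, out_size), min(cy + h, out_size)
        dw, dh = x2d - x1d, y2d - y1d
        if dw <= 0 or dh <= 0:
            continue
        # source crop anchored at the corner touching the centre
        x1s = w - dw if q in (0, 2) else 0
        y1s = h - dh if q in (0, 1) else 0
        canvas[y1d:y1d + dh, x1d:x1d + dw] = img[y1s:y1s + dh, x1s:x1s + dw]
        if len(boxes) == 0:
            continue
        # pixel boxes in source frame -> canvas frame
        bx = boxes[:, 1] * w - x1s + x1d
        by = boxes[:, 2] * h - y1s + y1d
        bw, bh = boxes[:, 3] * w, boxes[:, 4] * h
        x1 = np.clip(bx - bw / 2, x1d, x2d)
        y1 = np.clip(by - bh / 2, y1d, y2d)
        x2 = np.clip(bx + bw / 2, x1d, x2d)
        y2 = np.clip(by + bh / 2, y1d, y2d)
        area = (x2 - x1) * (y2 - y1)
        keep = area >= min_area_frac * bw * bh
        for c, a1, b1, a2, b2 in zip(boxes[keep, 0], x1[keep], y1[keep],
                                     x2[keep], y2[keep]):
            out_boxes.append([
                c, (a1 + a2) / 2 / out_size, (b1 + b2) / 2 / out_size,
                (a2 - a1) / out_size, (b2 - b1) / out_size,
            ])
    return LabeledImage(canvas, np.asarray(out_boxes, dtype=np.float64))


# --------------------------------------------------------------------------
# synthetic H&E-like vessel patches
# --------------------------------------------------------------------------

_EOSIN_BG = np.array([231, 180, 198], dtype=np.float64)     # pale eosin pink
_WALL = np.array([158, 84, 130], dtype=np.float64)          # vessel wall
_LUMEN = np.array([244, 232, 240], dtype=np.float64)        # near-empty lumen
_NUCLEUS = np.array([96, 60, 128], dtype=np.float64)        # hematoxylin dot


def _ellipse_mask(size, cx, cy, a, b, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_synthetic_sample(rng: np.random.Generator, n_vessels: int | None = None,
                              size: int = 512) -> LabeledImage:
    """One H&E-like patch with ring-shaped vessel objects and tight boxes.

    Vessels span 8-120 px across, with random eccentricity and rotation;
    nuclei-like dots and smooth pink texture form the background.  Fully
    deterministic given the generator state.
    """
    if n_vessels is None:
        n_vessels = int(rng.integers(0, 11))
    img = np.empty((size, size, 3), dtype=np.float64)
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), 12)
    texture = texture / (np.abs(texture).max() + 1e-9)
    for c in range(3):
        img[..., c] = _EOSIN_BG[c] + 14 * texture
    grain = rng.standard_normal((size, size, 1)) * 4.0
    img += grain

    # scattered nuclei
    for _ in range(int(rng.integers(40, 90))):
        cx, cy = rng.uniform(0, size, 2)
        r = rng.uniform(1.5, 4.0)
        mask = _ellipse_mask(size, cx, cy, r, r * rng.uniform(0.7, 1.0),
                             rng.uniform(0, np.pi))
        img[mask] = 0.35 * img[mask] + 0.65 * _NUCLEUS

    boxes = []
    occupied = np.zeros((size, size), dtype=bool)
    for _ in range(n_vessels):
        for _attempt in range(40):
            d = rng.uniform(8, 120)                       # major diameter, px
            a = d / 2
            b = a * rng.uniform(0.45, 1.0)                # eccentricity
            theta = rng.uniform(0, np.pi)
            margin = a + 2
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            outer = _ellipse_mask(size, cx, cy, a, b, theta)
            if not (outer & occupied).any():
                break
        wall_frac = rng.uniform(0.55, 0.8)
        inner = _ellipse_mask(size, cx, cy, a * wall_frac, b * wall_frac, theta)
        img[outer] = 0.2 * img[outer] + 0.8 * _WALL
        img[inner] = 0.25 * img[inner] + 0.75 * _LUMEN
        occupied |= outer
        ys, xs = np.nonzero(outer)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes.append([0, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                      (x2 - x1) / size, (y2 - y1) / size])

    img = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledImage(img, np.asarray(boxes, dtype=np.float64))


def write_synthetic_dataset(out_dir, n: int, seed: int = 0, size: int = 512):
    """Materialise a ready-to-train synthetic dataset with a YAML manifest."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for i in range(n):
        s = generate_synthetic_sample(rng, size=size)
        p = img_dir / f"synthetic_{i:05d}.png"
        Image.fromarray(s.image).save(p)
        write_label_file(p.with_suffix(".txt"), s.boxes)
    manifest = {"root": "images", "names": ["vessel"],   # relative to manifest
                "n_images": n, "seed": seed}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return out / "manifest.yaml"
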
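"""Synthetic axial brain-MRI phantom generator with instance labels.

Each phantom is a dark background carrying an elliptical "brain" with smooth
internal texture and exactly one tumor-like blob of one of two classes:

* class 0 (glioma surrogate): irregular star-convex outline, blurred rim,
  low contrast against the brain parenchyma;
* class 1 (meningioma surrogate): compact near-elliptical outline, sharp rim,
  high contrast.

Tumor centers are drawn uniformly from x in [0.2, 0.8], y in [0.2, 0.6] and
normalized box sizes from [0.2, 0.6], mirroring the annotation-distribution
characteristics of the clinical datasets the package emulates (head centered
in the field of view, medium-sized lesions, no edge targets).  Labels are
exact polygons; the raster mask is the polygon's rasterization, so label and
mask agree by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter, label as cc_label
from sklearn.model_selection import KFold

from .metrics import InstanceLabel

BRAIN_LEVEL = 85.0
TEXTURE_AMPLITUDE = 4.0
GLIOMA_DELTA = 50.0       # low-contrast class
MENINGIOMA_DELTA = 110.0  # high-contrast class


@dataclass
class PhantomParams:
    image_size: int = 640
    n_images: int = 64
    class_mix: float = 0.5        # probability of the meningioma surrogate
    center_range_x: tuple = (0.2, 0.8)
    center_range_y: tuple = (0.2, 0.6)
    size_range: tuple = (0.2, 0.6)
    noise_sigma: float = 6.0
    contrast: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.center_range_x, self.center_range_y, self.size_range):
            if not (0.0 <= r[0] <= r[1] <= 1.0):
                raise ValueError("ranges must lie within [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _star_polygon(rng, irregular: bool, n_vertices: int = 48) -> np.ndarray:
    """Unit star-convex polygon around the origin; radius modulated by random
    low-order harmonics (strongly for the glioma surrogate)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones(n_vertices)
    orders = range(2, 7) if irregular else range(2, 4)
    amp = (0.05, 0.13) if irregular else (0.01, 0.03)
    for k in orders:
        a = rng.uniform(*amp)
        phi = rng.uniform(0, 2 * np.pi)
        r += a * np.cos(k * theta + phi)
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def _fit_polygon_to_box(poly: np.ndarray, cx, cy, w, h) -> np.ndarray:
    """Affinely map a polygon so its bounding box is exactly (cx, cy, w, h)."""
    lo, hi = poly.min(axis=0), poly.max(axis=0)
    scale = np.array([w, h]) / (hi - lo)
    return (poly - lo) * scale + np.array([cx - w / 2, cy - h / 2])


def generate_phantom(params: PhantomParams, index: int):
    """Render phantom ``index``; returns (uint8 image (S, S), [InstanceLabel]).

    Fully determined by (params.seed, index).
    """
    if index >= params.n_images:
        raise IndexError(f"index {index} >= n_images {params.n_images}")
    rng = np.random.default_rng([params.seed, index])
    S = params.image_size
    img = np.full((S, S), 8.0)

    # brain ellipse with smooth internal texture
    yy, xx = np.mgrid[0:S, 0:S] / S
    bcx, bcy = 0.5 + rng.uniform(-0.01, 0.01, 2)
    ax, ay = 0.47 + rng.uniform(-0.01, 0.01), 0.50 + rng.uniform(-0.005, 0.005)
    rot = rng.uniform(-0.15, 0.15)
    xr = (xx - bcx) * np.cos(rot) + (yy - bcy) * np.sin(rot)
    yr = -(xx - bcx) * np.sin(rot) + (yy - bcy) * np.cos(rot)
    brain = (np.abs(xr / ax) ** 3.5 + np.abs(yr / ay) ** 3.5) <= 1.0  # squarish-oval axial outline
    texture = gaussian_filter(rng.standard_normal((S, S)), S / 16)
    texture *= TEXTURE_AMPLITUDE / max(texture.std(), 1e-9)
    img += brain * (BRAIN_LEVEL - 8.0 + texture)
    img = gaussian_filter(img, S / 320)

    # one tumor instance
    cls = int(rng.random() < params.class_mix)
    cx = rng.uniform(*params.center_range_x)
    cy = rng.uniform(*params.center_range_y)
    w = rng.uniform(*params.size_range)
    h = rng.uniform(*params.size_range)
    lo_sz = params.size_range[0]
    wmax = 2 * min(cx - 0.01, 0.99 - cx)
    hmax = 2 * min(cy - 0.01, 0.99 - cy)
    if w > wmax or h > hmax:
        if wmax < lo_sz or hmax < lo_sz:
            warnings.warn("tumor extent clipped below the configured size range")
        w, h = min(w, wmax), min(h, hmax)
    poly = _fit_polygon_to_box(_star_polygon(rng, irregular=(cls == 0)), cx, cy, w, h)
    label = InstanceLabel(class_id=cls, polygon=poly)
    mask = label.ensure_mask((S, S))

    delta = (MENINGIOMA_DELTA if cls else GLIOMA_DELTA) * params.contrast
    rim_sigma = S / 640 if cls else S / 320
    alpha = gaussian_filter(mask.astype(float), rim_sigma)
    img += alpha * (BRAIN_LEVEL + delta - img)  # composite to an absolute lesion level

    if params.noise_sigma > 0:
        img += rng.normal(0, params.noise_sigma, (S, S))
    return np.clip(np.round(img), 0, 255).astype(np.uint8), [label]


def generate_dataset(params: PhantomParams):
    """All phantoms of the configuration: (list of images, list of label lists)."""
    pairs = [generate_phantom(params, i) for i in range(params.n_images)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def external_shift(params: PhantomParams) -> PhantomParams:
    """Domain-shifted copy of the configuration (different scanner surrogate):
    lower contrast, heavier noise, fresh seed stream."""
    return PhantomParams(image_size=params.image_size, n_images=params.n_images,
                         class_mix=params.class_mix,
                         center_range_x=params.center_range_x,
                         center_range_y=params.center_range_y,
                         size_range=params.size_range,
                         noise_sigma=params.noise_sigma * 2.0 + 4.0,
                         contrast=params.contrast * 0.75,
                         seed=params.seed + 10_000)


def recover_mask_by_threshold(image: np.ndarray, label: InstanceLabel) -> np.ndarray:
    """Self-consistency oracle: segment the tumor by midpoint thresholding in
    a window around its box and keep the largest connected component."""
    S = image.shape[0]
    cx, cy, w, h = label.bbox
    x1 = max(int((cx - 0.75 * w) * S), 0)
    x2 = min(int((cx + 0.75 * w) * S), S)
    y1 = max(int((cy - 0.75 * h) * S), 0)
    y2 = min(int((cy + 0.75 * h) * S), S)
    crop = image[y1:y2, x1:x2].astype(float)
    thr = (crop.max() + BRAIN_LEVEL) / 2.0
    binary = np.zeros_like(image, dtype=bool)
    binary[y1:y2, x1:x2] = crop >= thr
    lab, n = cc_label(binary)
    if n == 0:
        return binary
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest


# -------------------------------------------------------------- preprocessing
def preprocess(image: np.ndarray, size: int = 640):
    """Letterbox to (size, size) with gray padding and scale to [0, 1].

    Returns (chw, meta): ``chw`` is float32 (3, size, size); ``meta`` holds
    the geometric transform for mapping label coordinates with
    :func:`transform_label`.
    """
    img = np.asarray(image)
    if img.size == 0 or min(img.shape[:2]) == 0:
        raise ValueError("zero-area image")
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    h, w = img.shape[:2]
    r = min(size / h, size / w)
    nh, nw = int(round(h * r)), int(round(w * r))
    resized = np.asarray(Image.fromarray(img.astype(np.uint8)).resize((nw, nh), Image.BILINEAR))
    top, left = (size - nh) // 2, (size - nw) // 2
    canvas = np.full((size, size, 3), 114, dtype=np.uint8)
    canvas[top:top + nh, left:left + nw] = resized
    chw = canvas.astype(np.float32).transpose(2, 0, 1) / 255.0
    meta = {"scale": r, "pad": (left, top), "orig_hw": (h, w), "size": size}
    return chw, meta


def transform_label(label: InstanceLabel, meta: dict) -> InstanceLabel:
    """Map a label from original-image normalized coordinates to the
    letterboxed frame."""
    h, w = meta["orig_hw"]
    r, (left, top), size = meta["scale"], meta["pad"], meta["size"]
    px = (label.polygon[:, 0] * w * r + left) / size
    py = (label.polygon[:, 1] * h * r + top) / size
    return InstanceLabel(class_id=label.class_id, polygon=np.stack([px, py], axis=1))


# ------------------------------------------------------------------ dataset IO
def write_dataset(images, labels, out_dir, class_names=("glioma", "meningioma"),
                  split: str = "train") -> Path:
    """Write PNG images, YOLO-segmentation label files (one ``class x1 y1
    x2 y2 ...`` line per instance, 6-decimal normalized coordinates) and a
    manifest YAML.  Returns the manifest path."""
    out = Path(out_dir)
    img_dir = out / "images" / split
    lab_dir = out / "labels" / split
    img_dir.mkdir(parents=True, exist_ok=True)
    lab_dir.mkdir(parents=True, exist_ok=True)
    for i, (img, labs) in enumerate(zip(images, labels)):
        Image.fromarray(img).save(img_dir / f"{i:06d}.png")
        lines = []
        for lab in labs:
            coords = " ".join(f"{v:.6f}" for v in lab.polygon.reshape(-1))
            lines.append(f"{lab.class_id} {coords}")
        (lab_dir / f"{i:06d}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    manifest = {"path": str(out.resolve()), "train": f"images/{split}",
                "names": {i: n for i, n in enumerate(class_names)},
                "nc": len(class_names)}
    mpath = out / "data.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_label_file(path) -> list[InstanceLabel]:
    labels = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls = int(parts[0])
        xy = np.asarray(parts[1:], dtype=np.float64).reshape(-1, 2)
        labels.append(InstanceLabel(class_id=cls, polygon=xy))
    return labels


def split_kfold(n_items: int, k: int, seed: int = 0):
    """Shuffled k-fold partition: fold i validates on subset i, trains on the
    rest; folds are disjoint and exhaustive."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_items:
        raise ValueError("k exceeds number of items")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train.tolist(), val.tolist()) for train, val in kf.split(np.arange(n_items))]
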
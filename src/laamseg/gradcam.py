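"""Grad-CAM heatmaps for the segmentation network.

The class-activation map of a chosen layer (default: the backbone-tail
module's output) is the rectified, gradient-weighted sum of its activation
channels: channel weights are the spatial average of the gradient of a target
score with respect to the activation.  The target score is the class logit of
the highest-confidence candidate for the requested class, which makes the map
answer "what drove this detection".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import zoom

from . import tensor as T
from .model import SegModel


@dataclass
class Heatmap:
    values: np.ndarray      # (H, W) in [0, 1]; min 0 and max 1 unless all-zero
    layer_name: str
    target: tuple           # (class id, flat candidate index)


def gradcam(model: SegModel, image: np.ndarray, layer_name: str = "tail",
            target_class: int | None = None) -> Heatmap:
    """Compute the Grad-CAM heatmap of ``layer_name`` for one image.

    ``image``: (3, H, W) in [0, 1].  When ``target_class`` is None the
    best-scoring class is used.  Returns an (H, W) map normalized to [0, 1]
    (all-zero, with a warning, when the score has no gradient at the layer).
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("image must be (3, H, W)")
    H, W = x.shape[1:]
    model.eval()
    preds, _ = model(T.Tensor(x[None]))
    if layer_name not in model._acts:
        raise KeyError(f"unknown layer {layer_name!r}; available: {sorted(model._acts)}")
    act = model._acts[layer_name]

    # locate the best candidate for the target class (confidence = obj * cls)
    flat_cls, flat_obj = [], []
    for p in preds:
        d = p.data.reshape(-1, model.no)
        flat_obj.append(d[:, 4])
        flat_cls.append(d[:, 5:5 + model.nc])
    obj = 1.0 / (1.0 + np.exp(-np.concatenate(flat_obj)))
    cls = 1.0 / (1.0 + np.exp(-np.concatenate(flat_cls, axis=0)))
    conf = obj[:, None] * cls
    if target_class is None:
        target_class = int(np.unravel_index(conf.argmax(), conf.shape)[1])
    best = int(conf[:, target_class].argmax())

    # differentiable score: the class logit of that candidate
    offset = 0
    score = None
    for p in preds:
        n_cells = int(np.prod(p.shape[:-1]))
        if best < offset + n_cells:
            local = best - offset
            flat = p.reshape(n_cells, model.no)
            score = flat[(np.array([local]), np.array([5 + target_class]))]
            break
        offset += n_cells
    model.zero_grad()
    score.backward(np.ones((1,), dtype=np.float32))
    grad = act.grad
    if grad is None or not np.any(grad):
        warnings.warn("zero gradient at the requested layer; returning empty heatmap")
        return Heatmap(np.zeros((H, W)), layer_name, (target_class, best))
    weights = grad[0].mean(axis=(1, 2))                      # GAP over space
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    cam = zoom(cam, (H / cam.shape[0], W / cam.shape[1]), order=1)
    cam -= cam.min()
    if cam.max() > 0:
        cam /= cam.max()
    return Heatmap(cam.astype(np.float64), layer_name, (target_class, best))


def overlay(image: np.ndarray, heatmap: Heatmap | np.ndarray, alpha: float = 0.5,
            path=None) -> np.ndarray:
    """Alpha-blend a colormapped heatmap onto a grayscale/RGB image.

    ``alpha`` = 0 returns the image, 1 the pure colormapped heatmap.  Returns
    the rendered uint8 RGB array and writes a PNG when ``path`` is given.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    from matplotlib import colormaps
    hm = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[0] in (1, 3):
        img = img.transpose(1, 2, 0)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[:2] != hm.shape:
        raise ValueError(f"shape mismatch: image {img.shape[:2]} vs heatmap {hm.shape}")
    if img.dtype != np.uint8:
        img = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    if img.shape[-1] == 1:
        img = np.repeat(img, 3, axis=-1)
    colored = (colormaps["jet"](hm)[..., :3] * 255).astype(np.uint8)
    out = np.clip((1 - alpha) * img.astype(np.float64) + alpha * colored, 0, 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(out).save(path)
    return out


def focus_score(heatmap: Heatmap | np.ndarray, mask: np.ndarray) -> float:
    """Ratio of mean heatmap mass inside a ground-truth mask to the mean mass
    outside it (area-normalized); > 1 means the map concentrates on the
    target region."""
    hm = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    m = np.asarray(mask, bool)
    inside = hm[m].mean() if m.any() else 0.0
    outside = hm[~m].mean() if (~m).any() else 0.0
    return float(inside / (outside + 1e-9))
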
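"""Detection/segmentation evaluation: greedy IoU matching, precision, recall,
average precision (area under the all-point interpolated PR curve) and mAP@50.

Matching is one-to-one within class: predictions are visited in order of
descending confidence and each takes the highest-IoU still-unmatched ground
truth with IoU >= threshold (TP), else counts as a false positive; leftover
ground truths are false negatives.  Matching can use mask IoU (default, the
segmentation task) or box IoU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .model import PredictionSet, box_iou_xyxy


@dataclass
class InstanceLabel:
    """One ground-truth object: class id, normalized polygon, derived
    normalized (cx, cy, w, h) box and raster mask at image resolution."""

    class_id: int
    polygon: np.ndarray          # (k, 2) normalized x, y
    bbox: np.ndarray = None      # (4,) normalized cx, cy, w, h
    mask: np.ndarray = None      # (H, W) bool

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.bbox is None:
            lo, hi = self.polygon.min(axis=0), self.polygon.max(axis=0)
            self.bbox = np.array([(lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2,
                                  hi[0] - lo[0], hi[1] - lo[1]])
        if np.any(self.bbox < -1e-9) or np.any(self.bbox > 1 + 1e-9):
            raise ValueError("bbox outside [0, 1]")

    def rasterize(self, hw: tuple) -> np.ndarray:
        """Raster mask of the polygon at resolution (H, W)."""
        h, w = hw
        rr, cc = draw_polygon(self.polygon[:, 1] * h, self.polygon[:, 0] * w, shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        return m

    def ensure_mask(self, hw: tuple) -> np.ndarray:
        if self.mask is None or self.mask.shape != tuple(hw):
            self.mask = self.rasterize(hw)
        return self.mask


@dataclass
class MatchCounts:
    tp: int
    fp: int
    fn: int
    ranked: list = field(default_factory=list)  # (confidence, is_tp, class_id) desc by confidence


@dataclass
class EvalReport:
    precision: float | None
    recall: float | None
    ap_per_class: dict
    map50: float
    matching_iou: float

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "ap_per_class": {int(k): v for k, v in self.ap_per_class.items()},
                "map50": self.map50, "matching_iou": self.matching_iou}


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a & b| / |a | b|; both-empty masks have no defined IoU."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks empty")
    return float(np.logical_and(a, b).sum() / union)


def _xywh_to_xyxy(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    return np.stack([b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2,
                     b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2], axis=1)


def _pairwise_iou(preds: PredictionSet, gts: list[InstanceLabel], use_masks: bool) -> np.ndarray:
    if len(preds) == 0 or not gts:
        return np.zeros((len(preds), len(gts)))
    if use_masks:
        hw = preds.masks.shape[1:]
        out = np.zeros((len(preds), len(gts)))
        gmasks = [g.ensure_mask(hw) for g in gts]
        for i in range(len(preds)):
            for j, gm in enumerate(gmasks):
                union = np.logical_or(preds.masks[i], gm).sum()
                inter = np.logical_and(preds.masks[i], gm).sum()
                out[i, j] = inter / union if union else 0.0
        return out
    pb = _xywh_to_xyxy(preds.boxes)
    gb = _xywh_to_xyxy(np.stack([g.bbox for g in gts]))
    return box_iou_xyxy(pb, gb)


def match(preds: PredictionSet, gts: list[InstanceLabel], iou_thr: float,
          use_masks: bool = True) -> MatchCounts:
    """Greedy one-to-one matching of one image's predictions to ground truth."""
    if not (0.0 < iou_thr <= 1.0):
        raise ValueError("iou_thr must be in (0, 1]")
    order = np.argsort(-np.asarray(preds.scores), kind="stable") if len(preds) else []
    iou = _pairwise_iou(preds, gts, use_masks)
    taken = np.zeros(len(gts), dtype=bool)
    ranked, tp = [], 0
    for i in order:
        cand = [j for j in range(len(gts))
                if not taken[j] and gts[j].class_id == preds.classes[i] and iou[i, j] >= iou_thr]
        if cand:
            j = max(cand, key=lambda j: iou[i, j])
            taken[j] = True
            tp += 1
            ranked.append((float(preds.scores[i]), True, int(preds.classes[i])))
        else:
            ranked.append((float(preds.scores[i]), False, int(preds.classes[i])))
    return MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, ranked=ranked)


def precision(c: MatchCounts) -> float | None:
    """TP / (TP + FP); None when no predictions were made."""
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None


def recall(c: MatchCounts) -> float | None:
    """TP / (TP + FN); None when there is no ground truth."""
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None


def average_precision(ranked_flags, n_gt: int) -> float | None:
    """Area under the PR curve, all-point interpolation.

    ``ranked_flags``: booleans ordered by descending confidence.  The
    precision envelope is made monotonically non-increasing from the right,
    then integrated over recall.  None when there is no ground truth.
    """
    if n_gt == 0:
        return None
    flags = np.asarray(ranked_flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    prec = tp_cum / np.arange(1, flags.size + 1)
    rec = tp_cum / n_gt
    env = np.maximum.accumulate(prec[::-1])[::-1]
    prev_r, ap = 0.0, 0.0
    for p, r in zip(env, rec):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def map_at_50(ap_per_class: dict) -> float:
    """Unweighted mean of the defined per-class APs."""
    vals = [v for v in ap_per_class.values() if v is not None]
    if not vals:
        raise ValueError("all per-class APs undefined")
    return float(np.mean(vals))


def evaluate_detections(preds_per_image: list[PredictionSet],
                        gts_per_image: list[list[InstanceLabel]],
                        matching_iou: float = 0.6,
                        ap_matching_iou: float | None = 0.5,
                        use_masks: bool = True) -> EvalReport:
    """Dataset-level report: precision/recall counted at ``matching_iou``; AP
    per class with matches declared at ``ap_matching_iou`` (defaults to the
    mAP@50 convention; pass None to reuse ``matching_iou``)."""
    if ap_matching_iou is None:
        ap_matching_iou = matching_iou
    tot = MatchCounts(0, 0, 0)
    ranked_ap, ngt_ap = [], {}
    classes = set()
    for preds, gts in zip(preds_per_image, gts_per_image):
        c = match(preds, gts, matching_iou, use_masks)
        tot.tp += c.tp
        tot.fp += c.fp
        tot.fn += c.fn
        ca = match(preds, gts, ap_matching_iou, use_masks)
        ranked_ap.extend(ca.ranked)
        for g in gts:
            ngt_ap[g.class_id] = ngt_ap.get(g.class_id, 0) + 1
            classes.add(g.class_id)
        classes.update(int(k) for k in preds.classes)
    ranked_ap.sort(key=lambda t: -t[0])
    ap = {}
    for c in sorted(classes):
        flags = [f for conf, f, cc in ranked_ap if cc == c]
        ap[c] = average_precision(flags, ngt_ap.get(c, 0))
    return EvalReport(precision=precision(tot), recall=recall(tot),
                      ap_per_class=ap, map50=map_at_50(ap), matching_iou=matching_iou)
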
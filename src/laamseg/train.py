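"""Desk-scale training and evaluation harness.

Training follows the YOLOv5 recipe: SGD with momentum 0.937 and weight decay
5e-4 on conv weights only, a short linear warmup, linear learning-rate decay
to 0.1x, anchor-ratio target assignment with neighbor-cell expansion, and a
composite loss (CIoU box + objectness BCE + class BCE + prototype-mask BCE
cropped to the instance box).

The tested configuration is deliberately small (tens of images, tens of
epochs, reduced input resolution and width) so a full train/eval cycle runs
on one CPU core in minutes; the full-scale protocol (640 px, 100 epochs,
batch 8) is reachable through the same configuration objects.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import tensor as T
from .metrics import EvalReport, InstanceLabel, evaluate_detections
from .model import ModelConfig, SegModel, build_model, forward_predict
from .nn import SGD, BatchNorm2d, Conv2d
from .phantom import PhantomParams, generate_phantom


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr0: float = 1e-2
    lrf: float = 0.1              # final lr fraction (linear decay)
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_iters: int = 20
    epochs: int = 100
    eval_iou_thresholds: tuple = (0.6, 0.7, 0.8, 0.9)
    box_gain: float = 0.05
    obj_iou_floor: float = 0.0   # objectness target = clip(CIoU, floor, 1)
    obj_gain: float = 1.0
    cls_gain: float = 0.5
    mask_gain: float = 1.0
    flip_augment: str = "hv"     # none|h|hv: mirrored replicas visited each epoch
    ema_decay: float = 0.99       # weight EMA (evaluated/saved weights)
    ema_tau: float = 100.0        # EMA warmup time constant, iterations
    conf_thr: float = 0.01        # evaluation-time confidence floor
    nms_iou: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")


@dataclass
class TimingReport:
    preprocess_ms: float
    inference_ms: float
    nms_ms: float

    def table(self) -> str:
        hdr = f"{'Pre-process Time (ms)':>22s}{'Inference Time (ms)':>22s}{'NMS Time (ms)':>16s}"
        row = f"{self.preprocess_ms:>22.2f}{self.inference_ms:>22.2f}{self.nms_ms:>16.2f}"
        return hdr + "\n" + row


class PhantomDataset:
    """In-memory dataset of phantoms rendered at the network input size."""

    def __init__(self, params: PhantomParams):
        self.params = params
        self.images, self.labels = [], []
        for i in range(params.n_images):
            img, labs = generate_phantom(params, i)
            self.images.append(np.stack([img] * 3).astype(np.float32) / 255.0)
            for l in labs:
                l.ensure_mask(img.shape)
            self.labels.append(labs)

    def __len__(self):
        return len(self.images)

    def input_hw(self):
        s = self.params.image_size
        return (s, s)


# ------------------------------------------------------------ loss machinery
def _bce_logits(x, t):
    """Numerically stable binary cross-entropy with logits (elementwise)."""
    absx = T.relu(x) + T.relu(x * -1.0)
    return T.relu(x) - x * t + T.log(T.exp(absx * -1.0) + 1.0)


def _ciou(pbox, tbox_np):
    """Complete IoU between predicted boxes (Tensor (P,4) xywh, grid units)
    and fixed targets (ndarray (P,4)).  Returns Tensor (P,)."""
    t = T.Tensor(tbox_np.astype(np.float32))
    px, py, pw, ph = pbox[:, 0], pbox[:, 1], pbox[:, 2], pbox[:, 3]
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = T.clamp(T.minimum(p_x2, t_x2) - T.maximum(p_x1, t_x1), 0.0, None)
    ih = T.clamp(T.minimum(p_y2, t_y2) - T.maximum(p_y1, t_y1), 0.0, None)
    inter = iw * ih
    union = pw * ph + tw * th - inter + 1e-7
    iou = inter / union
    cw = T.maximum(p_x2, t_x2) - T.minimum(p_x1, t_x1)
    ch = T.maximum(p_y2, t_y2) - T.minimum(p_y1, t_y1)
    c2 = cw * cw + ch * ch + 1e-7
    rho2 = (px - tx) ** 2.0 + (py - ty) ** 2.0
    v = (T.atan(tw / (th + 1e-7)) - T.atan(pw / (ph + 1e-7))) ** 2.0 * (4.0 / math.pi ** 2)
    with T.no_grad():
        alpha = v.data / (1.0 - iou.data + v.data + 1e-7)
    return iou - rho2 / c2 - v * T.Tensor(alpha.astype(np.float32))


def build_targets(model: SegModel, gt, input_hw):
    """YOLOv5 assignment: per scale, anchors within a 4x wh ratio of the
    target, center cell plus the two nearest neighbor cells.

    ``gt``: ndarray (n_gt, 6) rows [img, cls, cx, cy, w, h] normalized.
    Returns per-scale (b, a, gj, gi, tbox, tcls, anch, gt_idx).
    """
    out = []
    na = model.na
    g = 0.5
    off = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]], dtype=np.float32) * g
    H, W = input_hw
    for si, (stride, anchors) in enumerate(zip(model.strides, model.anchors)):
        h, w = H // stride, W // stride
        if len(gt) == 0:
            out.append(tuple(np.zeros(0, int) for _ in range(4)) + (np.zeros((0, 4)), np.zeros(0, int), np.zeros((0, 2)), np.zeros(0, int)))
            continue
        a_g = anchors / stride  # grid units
        t = np.concatenate([gt, np.arange(len(gt))[:, None]], axis=1)  # + gt index
        t = np.repeat(t[None], na, axis=0)                             # (na, n, 7)
        ai = np.tile(np.arange(na)[:, None], (1, len(gt)))
        txy = t[..., 2:4] * np.array([w, h])
        twh = t[..., 4:6] * np.array([w, h])
        r = twh / a_g[ai]
        keep = np.maximum(r, 1 / r).max(axis=2) < 4.0
        t, ai, txy, twh = t[keep], ai[keep], txy[keep], twh[keep]
        if len(t) == 0:
            out.append(tuple(np.zeros(0, int) for _ in range(4)) + (np.zeros((0, 4)), np.zeros(0, int), np.zeros((0, 2)), np.zeros(0, int)))
            continue
        # neighbor-cell expansion
        gxy = txy
        gxi = np.array([w, h]) - gxy
        jk = (gxy % 1 < g) & (gxy > 1)
        lm = (gxi % 1 < g) & (gxi > 1)
        sel = np.stack([np.ones(len(t), bool), jk[:, 0], jk[:, 1], lm[:, 0], lm[:, 1]])
        t_all = np.repeat(t[None], 5, axis=0)[sel]
        ai_all = np.repeat(ai[None], 5, axis=0)[sel]
        gxy_all = np.repeat(gxy[None], 5, axis=0)[sel]
        twh_all = np.repeat(twh[None], 5, axis=0)[sel]
        offs = np.repeat(off[:, None], len(t), axis=1)[sel]
        gij = (gxy_all - offs).astype(int)
        gi = np.clip(gij[:, 0], 0, w - 1)
        gj = np.clip(gij[:, 1], 0, h - 1)
        b = t_all[:, 0].astype(int)
        tcls = t_all[:, 1].astype(int)
        gt_idx = t_all[:, 6].astype(int)
        tbox = np.concatenate([gxy_all - gij, twh_all], axis=1)
        out.append((b, ai_all, gj, gi, tbox, tcls, a_g[ai_all], gt_idx))
    return out


def compute_loss(model: SegModel, preds, proto, gt, gt_masks, cfg: TrainConfig, input_hw):
    """Composite detection + segmentation loss; returns (Tensor scalar, dict)."""
    balance = (4.0, 1.0, 0.4)
    lbox = lobj = lcls = lseg = T.Tensor(np.float32(0.0), requires_grad=False)
    targets = build_targets(model, gt, input_hw)
    nm = model.nm
    ph, pw = proto.shape[2], proto.shape[3]
    n_pos = 0
    for si, (p, tgt) in enumerate(zip(preds, targets)):
        b, a, gj, gi, tbox, tcls, anch, gt_idx = tgt
        n, na, h, w, no = p.shape
        tobj = np.zeros((n, na, h, w), dtype=np.float32)
        if len(b):
            n_pos += len(b)
            ps = p[(b, a, gj, gi)]                       # (P, no)
            pxy = T.sigmoid(ps[:, 0:2]) * 2.0 - 0.5
            pwh = (T.sigmoid(ps[:, 2:4]) * 2.0) ** 2.0 * T.Tensor(anch.astype(np.float32))
            pbox = T.concat([pxy, pwh], axis=1)
            ciou = _ciou(pbox, tbox)
            lbox = lbox + (1.0 - ciou).mean()
            tobj[b, a, gj, gi] = np.clip(ciou.data, cfg.obj_iou_floor, 1.0)
            if model.nc > 1:
                tc = np.zeros((len(b), model.nc), dtype=np.float32)
                tc[np.arange(len(b)), tcls] = 1.0
                lcls = lcls + _bce_logits(ps[:, 5:5 + model.nc], T.Tensor(tc)).mean()
            # prototype masks
            coef = ps[:, 5 + model.nc:]
            boxes = gt[gt_idx][:, 2:6]                   # normalized xywh
            seg = T.Tensor(np.float32(0.0))
            for bi in np.unique(b):
                sel = np.flatnonzero(b == bi)
                pr = proto[int(bi)].reshape(nm, ph * pw)
                pm = coef[sel] @ pr                      # (Pb, ph*pw) logits
                gtm = gt_masks[gt_idx[sel]].reshape(len(sel), ph * pw)
                bce = _bce_logits(pm, T.Tensor(gtm.astype(np.float32)))
                crop = _box_crop_weights(boxes[sel], ph, pw)
                area = crop.sum(axis=1) + 1.0
                per = (bce * T.Tensor(crop)).sum(axis=1) / T.Tensor(area.astype(np.float32))
                seg = seg + per.sum()
            lseg = lseg + seg / float(len(b))
        obj_p = p[(Ellipsis, 4)]
        lobj = lobj + _bce_logits(obj_p, T.Tensor(tobj)).mean() * balance[si]
    total = cfg.box_gain * lbox + cfg.obj_gain * lobj + cfg.cls_gain * lcls + cfg.mask_gain * lseg
    parts = {"box": float(lbox.data), "obj": float(lobj.data),
             "cls": float(lcls.data), "seg": float(lseg.data), "n_pos": n_pos}
    return total, parts


def _box_crop_weights(boxes_norm: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Binary crop window per box at prototype resolution, flattened."""
    out = np.zeros((len(boxes_norm), ph, pw), dtype=np.float32)
    for i, (cx, cy, w, h) in enumerate(boxes_norm):
        x1 = max(int((cx - w / 2) * pw), 0)
        x2 = min(int(math.ceil((cx + w / 2) * pw)), pw)
        y1 = max(int((cy - h / 2) * ph), 0)
        y2 = min(int(math.ceil((cy + h / 2) * ph)), ph)
        out[i, y1:y2, x1:x2] = 1.0
    return out.reshape(len(boxes_norm), ph * pw)


def _dataset_targets(dataset: PhantomDataset, proto_hw):
    """Flatten dataset labels to the (img, cls, cx, cy, w, h) table plus
    prototype-resolution masks, once per training run."""
    rows, masks = [], []
    ph, pw = proto_hw
    H, W = dataset.input_hw()
    for i, labs in enumerate(dataset.labels):
        for l in labs:
            rows.append([i, l.class_id, *l.bbox])
            m = l.ensure_mask((H, W))
            fh, fw = H // ph, W // pw
            masks.append(m.reshape(ph, fh, pw, fw).mean(axis=(1, 3)) > 0.5)
    return np.asarray(rows, dtype=np.float64), np.asarray(masks, dtype=np.float32)


def recalibrate_bn(model: SegModel, images, max_images: int = 16):
    """Re-estimate batch-norm running statistics with one large-batch forward
    pass in training mode.  Small-batch training leaves running averages far
    from the statistics the fitted weights expect; recalibrating on (a subset
    of) the training images restores eval-mode behavior."""
    bns = []
    stack = [model]
    while stack:
        m = stack.pop()
        if isinstance(m, BatchNorm2d):
            bns.append(m)
        stack.extend(c for _, c in m._children())
    saved = [b.momentum for b in bns]
    for b in bns:
        b.momentum = 1.0
    model.train()
    try:
        model(T.Tensor(np.stack(images[:max_images])))
    finally:
        for b, mo in zip(bns, saved):
            b.momentum = mo


def save_checkpoint(model: SegModel, path, extra: dict | None = None):
    payload = {f"param::{k}": v for k, v in model.state_dict().items()}
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **payload)


def load_checkpoint(path) -> tuple[SegModel, dict]:
    z = np.load(path)
    meta = json.loads(bytes(z["__meta__"]).decode())
    model = build_model(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict({k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")})
    return model, meta["extra"]


def train(model: SegModel, dataset: PhantomDataset, cfg: TrainConfig,
          checkpoint_path=None, log=None):
    """Train in place; returns the history (one dict per epoch).

    Saves the best-by-mAP@50 checkpoint when ``checkpoint_path`` is given.
    Aborts with a diagnostic if the loss goes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    for labs in dataset.labels:
        for l in labs:
            if l.class_id >= model.nc:
                raise ValueError("label class id exceeds model class count")
    rng = np.random.default_rng(cfg.seed)
    decay_params, plain_params = [], []
    seen = set()

    def collect(m):
        if isinstance(m, Conv2d):
            decay_params.append(m.weight)
            if m.bias is not None:
                plain_params.append(m.bias)
            seen.update((id(m.weight), id(m.bias) if m.bias is not None else 0))

    stack = [model]
    while stack:
        m = stack.pop()
        collect(m)
        stack.extend(c for _, c in m._children())
    for p in model.parameters():
        if id(p) not in seen and not any(p is q for q in decay_params + plain_params):
            plain_params.append(p)

    opt = SGD(decay_params, lr=cfg.lr0, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    opt.add_group(plain_params, lr=cfg.lr0, momentum=cfg.momentum, weight_decay=0.0)

    H, W = dataset.input_hw()
    ph, pw = H // 4, W // 4
    gt, gt_masks = _dataset_targets(dataset, (ph, pw))
    history, best_map, it = [], -1.0, 0
    n = len(dataset)
    params = dict(model.named_parameters())
    ema = {k: p.data.copy() for k, p in params.items()}

    def ema_update():
        d = cfg.ema_decay * (1.0 - math.exp(-it / cfg.ema_tau))
        for k, p in params.items():
            ema[k] *= d
            ema[k] += (1.0 - d) * p.data

    def with_ema(fn):
        backup = {k: p.data.copy() for k, p in params.items()}
        for k, p in params.items():
            p.data[...] = ema[k]
        recalibrate_bn(model, dataset.images)
        try:
            return fn()
        finally:
            for k, p in params.items():
                p.data[...] = backup[k]

    for epoch in range(cfg.epochs):
        model.train()
        # each epoch visits every image plus its mirrored replicas
        flips = [(False, False)]
        if cfg.flip_augment in ("h", "hv"):
            flips.append((True, False))
        if cfg.flip_augment == "hv":
            flips += [(False, True), (True, True)]
        samples = [(i, fh, fv) for i in range(n) for fh, fv in flips]
        order = rng.permutation(len(samples))
        frac = 1.0 - epoch / max(cfg.epochs, 1)
        base_lr = cfg.lr0 * (frac * (1 - cfg.lrf) + cfg.lrf)
        losses = []
        for s in range(0, len(samples), cfg.batch_size):
            chunk = [samples[j] for j in order[s:s + cfg.batch_size]]
            it += 1
            lr = base_lr * min(it / max(cfg.warmup_iters, 1), 1.0)
            for g in opt.param_groups:
                g["lr"] = lr
            imgs, rows, mrows = [], [], []
            for bi, (i, fh, fv) in enumerate(chunk):
                im = dataset.images[i]
                if fh:
                    im = im[:, :, ::-1]
                if fv:
                    im = im[:, ::-1, :]
                imgs.append(im)
                for r in np.flatnonzero(gt[:, 0] == i):
                    row = gt[r].copy()
                    row[0] = bi
                    m = gt_masks[r]
                    if fh:
                        row[2] = 1.0 - row[2]
                        m = m[:, ::-1]
                    if fv:
                        row[3] = 1.0 - row[3]
                        m = m[::-1, :]
                    rows.append(row)
                    mrows.append(m)
            x = T.Tensor(np.ascontiguousarray(np.stack(imgs)))
            bt = np.stack(rows)
            preds, proto = model(x)
            loss, parts = compute_loss(model, preds, proto, bt, np.stack(mrows), cfg, (H, W))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, images {[c[0] for c in chunk]}: {parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ema_update()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr}
        if epoch == cfg.epochs - 1 or (epoch + 1) % 5 == 0:
            rep = with_ema(lambda: evaluate(model, dataset, (0.5,), cfg)[0.5])
            entry["map50"] = rep.map50
            if rep.map50 >= best_map:
                best_map = rep.map50
                if checkpoint_path is not None:
                    with_ema(lambda: save_checkpoint(
                        model, checkpoint_path, {"epoch": epoch, "map50": best_map}))
        history.append(entry)
        if log is not None:
            log(entry)
    # the averaged weights are the deliverable, as in the reference recipe
    for k, p in params.items():
        p.data[...] = ema[k]
    recalibrate_bn(model, dataset.images)
    return history


def evaluate(model: SegModel, dataset: PhantomDataset, thresholds=None,
             cfg: TrainConfig | None = None, use_masks: bool = True) -> dict[float, EvalReport]:
    """Forward + NMS + matching at each IoU threshold; {threshold: EvalReport}."""
    cfg = cfg or TrainConfig()
    thresholds = thresholds or cfg.eval_iou_thresholds
    x = np.stack(dataset.images)
    preds = forward_predict(model, x, conf_thr=cfg.conf_thr, nms_iou=cfg.nms_iou)
    out = {}
    for thr in thresholds:
        out[thr] = evaluate_detections(preds, dataset.labels, matching_iou=thr,
                                       ap_matching_iou=0.5, use_masks=use_masks)
    return out


def thresholds_table(reports: dict[float, EvalReport]) -> str:
    lines = [f"{'IoU':>5s}{'Precision':>11s}{'Recall':>9s}{'mAP@50':>9s}"]
    for thr, r in sorted(reports.items()):
        p = "n/a" if r.precision is None else f"{r.precision:.3f}"
        rr = "n/a" if r.recall is None else f"{r.recall:.3f}"
        lines.append(f"{thr:>5.2f}{p:>11s}{rr:>9s}{r.map50:>9.3f}")
    return "\n".join(lines)


def timing_breakdown(model: SegModel, dataset: PhantomDataset, n_warmup: int = 1,
                     conf_thr: float = 0.25, nms_iou: float = 0.45) -> TimingReport:
    """Per-image means of the pre-process / inference / NMS phases."""
    if n_warmup < 1:
        raise ValueError("n_warmup must be >= 1")
    from .model import decode_predictions, nms as run_nms
    model.eval()
    H, W = dataset.input_hw()
    tp = ti = tn = 0.0
    counted = 0
    for rep in range(n_warmup + 1):
        warm = rep < n_warmup
        for i in range(len(dataset)):
            t0 = time.perf_counter()
            raw = (dataset.images[i] * 255).astype(np.uint8)
            x = raw.astype(np.float32)[None] / 255.0
            t1 = time.perf_counter()
            with T.no_grad():
                preds, proto = model(T.Tensor(x))
            rows = decode_predictions(model, preds, (H, W))
            t2 = time.perf_counter()
            r = rows[0]
            conf = (r[:, 4:5] * r[:, 5:5 + model.nc])
            score = conf.max(axis=1)
            keep = score >= conf_thr
            r, score = r[keep], score[keep]
            if len(r):
                xyxy = np.stack([r[:, 0] - r[:, 2] / 2, r[:, 1] - r[:, 3] / 2,
                                 r[:, 0] + r[:, 2] / 2, r[:, 1] + r[:, 3] / 2], axis=1)
                run_nms(xyxy, score, nms_iou)
            t3 = time.perf_counter()
            if not warm:
                tp += t1 - t0
                ti += t2 - t1
                tn += t3 - t2
                counted += 1
    k = max(counted, 1)
    return TimingReport(preprocess_ms=tp / k * 1e3, inference_ms=ti / k * 1e3, nms_ms=tn / k * 1e3)
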
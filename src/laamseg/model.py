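"""YOLOv5s-style instance-segmentation network with a replaceable backbone tail.

Layout: CSP/C3 backbone, PANet neck, anchor-based detection head with a
prototype-mask segmentation branch (32 prototypes at 1/4 input resolution).
The spatial-pyramid slot at the backbone tail (stride 32) accepts any variant
from :mod:`laamseg.modules`; its input/output widths equal the original SPP
slot widths so the neck wiring is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .modules import ModuleSpec, build_variant
from .nn import Conv2d, ConvBnAct, Module, Sequential, Upsample, init_seed

# anchor widths/heights in pixels at stride 8/16/32 (standard v5 priors)
ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)
STRIDES = (8, 16, 32)


def make_divisible(x: float, d: int = 8) -> int:
    return max(d, int(math.ceil(x / d) * d))


@dataclass
class ModelConfig:
    input_size: tuple = (640, 640)
    num_classes: int = 2
    tail_variant: ModuleSpec | str = "SPP"
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    num_masks: int = 32
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError("input_size must be divisible by 32")

    def to_dict(self) -> dict:
        tv = self.tail_variant
        return {
            "input_size": list(self.input_size),
            "num_classes": self.num_classes,
            "tail_variant": tv.to_dict() if isinstance(tv, ModuleSpec) else tv,
            "depth_multiple": self.depth_multiple,
            "width_multiple": self.width_multiple,
            "num_masks": self.num_masks,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["input_size"] = tuple(d.get("input_size", (640, 640)))
        tv = d.get("tail_variant", "SPP")
        if isinstance(tv, dict):
            d["tail_variant"] = ModuleSpec.from_dict(tv)
        return cls(**d)


@dataclass
class PredictionSet:
    """Per-image model output after confidence filtering and NMS."""

    boxes: np.ndarray      # (k, 4) normalized cx, cy, w, h
    scores: np.ndarray     # (k,)
    classes: np.ndarray    # (k,) int
    masks: np.ndarray      # (k, H, W) bool, at network input resolution

    def __len__(self):
        return len(self.scores)


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True):
        super().__init__()
        self.cv1 = ConvBnAct(c1, c2, 1)
        self.cv2 = ConvBnAct(c2, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def complexity(self, in_shape):
        s, e1 = self.cv1.complexity(in_shape)
        s, e2 = self.cv2.complexity(s)
        return s, e1 + e2


class C3(Module):
    """CSP bottleneck block with three 1x1 convolutions."""

    def __init__(self, c1, c2, n=1, shortcut=True):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c1, c_, 1)
        self.m = [Bottleneck(c_, c_, shortcut) for _ in range(n)]
        self.cv3 = ConvBnAct(2 * c_, c2, 1)

    def forward(self, x):
        a = self.cv1(x)
        for b in self.m:
            a = b(a)
        return self.cv3(T.concat([a, self.cv2(x)], axis=1))

    def complexity(self, in_shape):
        s, e = self.cv1.complexity(in_shape)
        entries = [("cv1." + n, p, f) for n, p, f in e]
        for i, b in enumerate(self.m):
            s, e = b.complexity(s)
            entries += [(f"m{i}." + n, p, f) for n, p, f in e]
        _, e = self.cv2.complexity(in_shape)
        entries += [("cv2." + n, p, f) for n, p, f in e]
        out, e = self.cv3.complexity((2 * s[0], s[1], s[2]))
        return out, entries + [("cv3." + n, p, f) for n, p, f in e]


class Proto(Module):
    """Mask-prototype branch from the stride-8 feature map (output stride 4)."""

    def __init__(self, c1, c_, nm):
        super().__init__()
        self.cv1 = ConvBnAct(c1, c_, 3)
        self.up = Upsample(2)
        self.cv2 = ConvBnAct(c_, c_, 3)
        self.cv3 = ConvBnAct(c_, nm, 1)

    def forward(self, x):
        return self.cv3(self.cv2(self.up(self.cv1(x))))

    def complexity(self, in_shape):
        s, e1 = self.cv1.complexity(in_shape)
        s, _ = self.up.complexity(s)
        s, e2 = self.cv2.complexity(s)
        out, e3 = self.cv3.complexity(s)
        return out, e1 + e2 + e3


class SegModel(Module):
    """Backbone + neck + segmentation head; ``forward`` returns raw per-scale
    predictions of shape (n, na, h, w, 5 + nc + nm) plus mask prototypes."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        gd = lambda n: max(round(n * cfg.depth_multiple), 1)
        gw = lambda c: make_divisible(c * cfg.width_multiple, 8)
        c64, c128, c256, c512, c1024 = gw(64), gw(128), gw(256), gw(512), gw(1024)
        self.nc, self.nm = cfg.num_classes, cfg.num_masks
        self.no = 5 + self.nc + self.nm
        self.na = 3
        self.strides = STRIDES
        self.anchors = np.asarray(ANCHORS, dtype=np.float32)

        tv = cfg.tail_variant
        if isinstance(tv, str):
            tail_spec = ModuleSpec(tv, in_channels=c1024, out_channels=c1024)
        else:
            tail_spec = ModuleSpec(tv.variant, in_channels=c1024, out_channels=c1024,
                                   dilation_rates=tv.dilation_rates,
                                   channel_reduction=tv.channel_reduction,
                                   branch_width_ratio=tv.branch_width_ratio)
        self.tail_spec = tail_spec

        with init_seed(cfg.seed):
            # backbone
            self.b0 = ConvBnAct(3, c64, 6, 2, p=2)
            self.b1 = ConvBnAct(c64, c128, 3, 2)
            self.b2 = C3(c128, c128, gd(3))
            self.b3 = ConvBnAct(c128, c256, 3, 2)
            self.b4 = C3(c256, c256, gd(6))
            self.b5 = ConvBnAct(c256, c512, 3, 2)
            self.b6 = C3(c512, c512, gd(9))
            self.b7 = ConvBnAct(c512, c1024, 3, 2)
            self.b8 = C3(c1024, c1024, gd(3))
            self.tail = build_variant(tail_spec)
            # neck (PANet)
            self.n10 = ConvBnAct(c1024, c512, 1)
            self.up = Upsample(2)
            self.n13 = C3(c1024, c512, gd(3), shortcut=False)
            self.n14 = ConvBnAct(c512, c256, 1)
            self.n17 = C3(c512, c256, gd(3), shortcut=False)
            self.n18 = ConvBnAct(c256, c256, 3, 2)
            self.n20 = C3(c512, c512, gd(3), shortcut=False)
            self.n21 = ConvBnAct(c512, c512, 3, 2)
            self.n23 = C3(c1024, c1024, gd(3), shortcut=False)
            # head
            self.proto = Proto(c256, c256, self.nm)  # prototype hidden width follows the stride-8 width
            self.det = [Conv2d(c, self.na * self.no, 1) for c in (c256, c512, c1024)]
        self._init_det_biases()
        self._tail_out = None   # captured activations for Grad-CAM
        self._acts = {}

    def _init_det_biases(self):
        h = self.cfg.input_size[0]
        for conv, s in zip(self.det, self.strides):
            b = conv.bias.data.reshape(self.na, self.no)
            b[:, 4] += math.log(8.0 / (h / s) ** 2)          # objectness prior
            b[:, 5:5 + self.nc] += math.log(0.6 / (self.nc - 0.99 + 1e-9))
            conv.bias.data[...] = b.reshape(-1)

    # ------------------------------------------------------------- forward
    def forward(self, x):
        x1 = self.b1(self.b0(x))
        x2 = self.b2(x1)
        x4 = self.b4(self.b3(x2))
        x6 = self.b6(self.b5(x4))
        x8 = self.b8(self.b7(x6))
        t = self.tail(x8)
        self._tail_out = t
        self._acts = {"backbone_p3": x4, "backbone_p4": x6, "backbone_p5": x8, "tail": t}
        n10 = self.n10(t)
        n13 = self.n13(T.concat([self.up(n10), x6], axis=1))
        n14 = self.n14(n13)
        p3 = self.n17(T.concat([self.up(n14), x4], axis=1))
        p4 = self.n20(T.concat([self.n18(p3), n14], axis=1))
        p5 = self.n23(T.concat([self.n21(p4), n10], axis=1))
        proto = self.proto(p3)
        preds = []
        for conv, p in zip(self.det, (p3, p4, p5)):
            y = conv(p)
            n, _, h, w = y.shape
            y = y.reshape(n, self.na, self.no, h, w).transpose(0, 1, 3, 4, 2)
            preds.append(y)
        return preds, proto

    # ---------------------------------------------------------- complexity
    def complexity(self, in_shape=None):
        if in_shape is None:
            in_shape = (3, *self.cfg.input_size)
        entries = []

        def walk(name, mod, s):
            out, e = mod.complexity(s)
            entries.extend([(f"{name}.{n}", p, f) for n, p, f in e])
            return out

        s = walk("b0", self.b0, in_shape)
        s = walk("b1", self.b1, s)
        s2 = walk("b2", self.b2, s)
        s = walk("b3", self.b3, s2)
        s4 = walk("b4", self.b4, s)
        s = walk("b5", self.b5, s4)
        s6 = walk("b6", self.b6, s)
        s = walk("b7", self.b7, s6)
        s8 = walk("b8", self.b8, s)
        st = walk("tail", self.tail, s8)
        s10 = walk("n10", self.n10, st)
        u, _ = self.up.complexity(s10)
        s13 = walk("n13", self.n13, (u[0] + s6[0], u[1], u[2]))
        s14 = walk("n14", self.n14, s13)
        u, _ = self.up.complexity(s14)
        p3 = walk("n17", self.n17, (u[0] + s4[0], u[1], u[2]))
        d = walk("n18", self.n18, p3)
        p4 = walk("n20", self.n20, (d[0] + s14[0], d[1], d[2]))
        d = walk("n21", self.n21, p4)
        p5 = walk("n23", self.n23, (d[0] + s10[0], d[1], d[2]))
        walk("proto", self.proto, p3)
        for i, (conv, ps) in enumerate(zip(self.det, (p3, p4, p5))):
            walk(f"det{i}", conv, ps)
        return entries


def build_model(cfg: ModelConfig) -> SegModel:
    """Assemble the segmentation network with the configured tail variant."""
    return SegModel(cfg)


# ------------------------------------------------------------------ inference
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode_predictions(model: SegModel, preds, input_hw) -> np.ndarray:
    """Raw head outputs -> (n, total, 5+nc+nm) rows of [cx, cy, w, h (pixels),
    obj, cls..., maskcoef...]; sigmoids applied, v5 box parameterization."""
    out = []
    for p, stride, anchors in zip(preds, model.strides, model.anchors):
        a = p.data if isinstance(p, T.Tensor) else p
        n, na, h, w, no = a.shape
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        grid = np.stack([gx, gy], axis=-1).astype(np.float32)  # (h, w, 2)
        s = _sigmoid(a[..., :5 + model.nc])
        xy = (s[..., 0:2] * 2.0 - 0.5 + grid) * stride
        wh = (s[..., 2:4] * 2.0) ** 2 * anchors.reshape(1, na, 1, 1, 2)
        rest = a[..., 5 + model.nc:]
        rows = np.concatenate([xy, wh, s[..., 4:5], s[..., 5:5 + model.nc], rest], axis=-1)
        out.append(rows.reshape(n, na * h * w, no))
    return np.concatenate(out, axis=1)


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (n,4) and (m,4) corner-format boxes."""
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.clip(br - tl, 0, None), axis=2)
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-9)


def nms(boxes_xyxy: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy NMS; suppression only for overlap strictly above ``iou_thr``,
    so iou_thr=1.0 retains every candidate."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = box_iou_xyxy(boxes_xyxy[i:i + 1], boxes_xyxy[order[1:]])[0]
        order = order[1:][ious <= iou_thr]
    return np.asarray(keep, dtype=int)


def forward_predict(model: SegModel, images, conf_thr: float = 0.25,
                    nms_iou: float = 0.45, max_det: int = 100,
                    merge: bool = True, mask_nms_iou: float = 0.5,
                    agnostic: bool = True) -> list[PredictionSet]:
    """Run the network and post-process to per-image prediction sets.

    ``images``: (n, 3, H, W) in [0, 1].  Masks are assembled from the
    prototype bank, cropped to their boxes, upsampled to (H, W) and
    thresholded at 0.5.

    With ``merge`` (default), each NMS survivor's box and mask coefficients
    are replaced by the confidence-weighted mean over its suppressed cluster
    (weighted fusion), which stabilizes boxes produced by duplicate
    candidates of varying shape.  Because instances are matched by mask
    overlap, a second suppression pass runs in mask space: survivors whose
    binary mask overlaps a kept higher-confidence mask of the same class by
    more than ``mask_nms_iou`` are dropped (set to 1.0 to disable).
    ``agnostic`` applies both suppression passes across classes, appropriate
    when instances of different classes cannot spatially coincide (one lesion
    has one type).
    """
    x = images.data if isinstance(images, T.Tensor) else np.asarray(images)
    if x.max() > 1.0 + 1e-3:
        raise ValueError("images must be normalized to [0, 1]")
    n, _, H, W = x.shape
    model.eval()
    with T.no_grad():
        preds, proto = model(T.Tensor(x.astype(np.float32)))
    rows = decode_predictions(model, preds, (H, W))
    proto_np = proto.data  # (n, nm, H/4, W/4)
    results = []
    for i in range(n):
        r = rows[i]
        conf = r[:, 4:5] * r[:, 5:5 + model.nc]
        cls = conf.argmax(axis=1)
        score = conf.max(axis=1)
        m = score >= conf_thr
        r, cls, score = r[m], cls[m], score[m]
        if len(r) == 0:
            results.append(PredictionSet(np.zeros((0, 4)), np.zeros(0), np.zeros(0, int),
                                         np.zeros((0, H, W), bool)))
            continue
        xyxy = np.stack([r[:, 0] - r[:, 2] / 2, r[:, 1] - r[:, 3] / 2,
                         r[:, 0] + r[:, 2] / 2, r[:, 1] + r[:, 3] / 2], axis=1)
        keep = []
        if agnostic:
            keep = list(nms(xyxy, score, nms_iou))
        else:
            for c in np.unique(cls):
                idx = np.flatnonzero(cls == c)
                kept = nms(xyxy[idx], score[idx], nms_iou)
                keep.extend(idx[kept])
        keep = np.asarray(sorted(keep, key=lambda j: -score[j])[:max_det], dtype=int)
        coef_all = r[:, 5 + model.nc:]
        if merge and len(keep):
            iou_all = box_iou_xyxy(xyxy[keep], xyxy)
            fused_xyxy, fused_coef = [], []
            for row, ki in zip(iou_all, keep):
                m_ = (row > nms_iou) if agnostic else ((row > nms_iou) & (cls == cls[ki]))
                wgt = score[m_][:, None]
                fused_xyxy.append((xyxy[m_] * wgt).sum(axis=0) / wgt.sum())
                fused_coef.append((coef_all[m_] * wgt).sum(axis=0) / wgt.sum())
            xyxy = np.asarray(fused_xyxy)
            coef = np.asarray(fused_coef)
            r, cls, score = r[keep], cls[keep], score[keep]
        else:
            r, cls, score, xyxy = r[keep], cls[keep], score[keep], xyxy[keep]
            coef = coef_all[keep]
        pm = _sigmoid(np.einsum("km,mhw->khw", coef, proto_np[i]))
        # crop to box at proto resolution, then upsample x4 and threshold
        ph, pw = pm.shape[1:]
        masks = np.zeros((len(r), H, W), dtype=bool)
        for k in range(len(r)):
            up = pm[k].repeat(4, axis=0).repeat(4, axis=1)[:H, :W]
            x1, y1, x2, y2 = xyxy[k]
            box_mask = np.zeros((H, W), bool)
            xs = slice(max(int(x1), 0), min(int(math.ceil(x2)), W))
            ys = slice(max(int(y1), 0), min(int(math.ceil(y2)), H))
            box_mask[ys, xs] = True
            masks[k] = (up > 0.5) & box_mask
        if mask_nms_iou < 1.0 and len(r) > 1:
            order = np.argsort(-score, kind="stable")
            kept: list[int] = []
            for k in order:
                dup = False
                for j in kept:
                    if not agnostic and cls[j] != cls[k]:
                        continue
                    union = np.logical_or(masks[j], masks[k]).sum()
                    if union and np.logical_and(masks[j], masks[k]).sum() / union > mask_nms_iou:
                        dup = True
                        break
                if not dup:
                    kept.append(k)
            kept = sorted(kept, key=lambda j: -score[j])
            r, cls, score, xyxy, masks = r[kept], cls[kept], score[kept], xyxy[kept], masks[kept]
        cxcywh = np.stack([(xyxy[:, 0] + xyxy[:, 2]) / 2, (xyxy[:, 1] + xyxy[:, 3]) / 2,
                           xyxy[:, 2] - xyxy[:, 0], xyxy[:, 3] - xyxy[:, 1]], axis=1)
        boxes = cxcywh / np.array([W, H, W, H])
        results.append(PredictionSet(boxes, score, cls, masks))
    return results
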
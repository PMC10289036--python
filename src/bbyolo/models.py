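"""Detector assembly: the four-scale lightweight detector and the YOLOv5x baseline.

The main model ("BlueberryYOLO") uses a MobileNetV3-style backbone whose CSP
blocks carry Little-CBAM attention, a PAN neck extended by a stride-4 (P2)
detection level for small berries — grids 152/76/38/19 at the native 608
input — and an MSSENet channel-attention block on each head input.  The
reference YOLOv5x (v6-generation layout: 6x6 stem, C3 blocks, SPPF) is kept
for parameter/FLOP comparison and ablation parity.

Also here: prediction decoding, per-class greedy NMS, and the profiler that
counts trainable parameters and forward GFLOPs (2 FLOPs per multiply-
accumulate) by shape propagation through the real forward code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import _stable_sigmoid
from .anchors import AnchorSet, YOLOV5_COCO_ANCHORS, default_anchors
from .blocks import C3, C3Mobile, MSSENet, SPPF
from .nn import ConvBnAct, Conv2d, Module, ModuleList, Shadow, Tensor
from .voc import Detection

__all__ = [
    "DetectorConfig", "BlueberryYOLO", "YOLOv5", "Detect",
    "build_blueberry_yolo", "build_yolov5x",
    "decode_predictions", "nms", "profile_model",
]


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(int(math.ceil(x / divisor) * divisor), divisor)


@dataclass
class DetectorConfig:
    """Build-time configuration of a detector."""

    input_size: int = 608
    n_classes: int = 3
    anchors: AnchorSet | None = None
    width_multiple: float = 1.0
    depth_multiple: float = 1.0
    backbone: str = "mobilenetv3_littlecbam"
    head_attention: str = "mssenet"
    neck_levels: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.neck_levels not in (3, 4):
            raise ValueError("neck_levels must be 3 or 4")
        if self.backbone not in ("mobilenetv3_littlecbam", "yolov5x_csp"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.head_attention not in ("none", "mssenet"):
            raise ValueError(f"unknown head_attention {self.head_attention!r}")


def _largest_divisor(c: int, cap: int = 16) -> int:
    for r in range(min(cap, c), 0, -1):
        if c % r == 0:
            return r
    return 1


class Detect(Module):
    """Per-level 1x1 prediction convs emitting anchors*(5+nc) maps."""

    def __init__(self, channels, n_classes: int, per_scale: int = 3):
        super().__init__()
        self.n_classes = n_classes
        self.per_scale = per_scale
        self.convs = ModuleList([
            Conv2d(c, per_scale * (5 + n_classes), 1, bias=True) for c in channels])
        no = 5 + n_classes
        for conv in self.convs:
            # start objectness rare and class logits mild for stable training
            bias = conv.bias.data.reshape(per_scale, no)
            bias[:, 4] = -4.5
            bias[:, 5:] = -2.0

    def forward(self, features):
        return [conv(x) for conv, x in zip(self.convs, features)]


class BlueberryYOLO(Module):
    """Four-scale lightweight detector (strides 4, 8, 16, 32)."""

    BASE_WIDTHS = (32, 64, 128, 256, 512)  # stem, P2, P3, P4, P5
    BASE_DEPTHS = (2, 3, 3, 2)             # backbone C3Mobile repeats
    HEAD_WIDTH_CAP = 128                   # channels entering MSSENet heads

    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        if cfg.neck_levels != 4:
            raise ValueError("the four-scale detector requires neck_levels=4")
        anchors = cfg.anchors if cfg.anchors is not None else default_anchors()
        if anchors.n_levels * anchors.per_scale != 12:
            raise ValueError("expected 4 scales x 3 anchors = 12 priors")
        nn.seed_rng(cfg.seed)
        self.cfg = cfg
        self.anchor_set = anchors
        self.strides = (4, 8, 16, 32)
        self.n_classes = cfg.n_classes

        gw, gd = cfg.width_multiple, cfg.depth_multiple
        div = 8 if gw >= 0.5 else 2
        c = [make_divisible(w * gw, div) for w in self.BASE_WIDTHS]
        d = [max(round(n * gd), 1) for n in self.BASE_DEPTHS]
        act = "hswish"

        # backbone
        self.stem = ConvBnAct(3, c[0], 3, 2, act=act)
        self.down2 = ConvBnAct(c[0], c[1], 3, 2, act=act)
        self.stage2 = C3Mobile(c[1], c[1], d[0], act=act)
        self.down3 = ConvBnAct(c[1], c[2], 3, 2, act=act)
        self.stage3 = C3Mobile(c[2], c[2], d[1], act=act)
        self.down4 = ConvBnAct(c[2], c[3], 3, 2, act=act)
        self.stage4 = C3Mobile(c[3], c[3], d[2], act=act)
        self.down5 = ConvBnAct(c[3], c[4], 3, 2, act=act)
        self.stage5 = C3Mobile(c[4], c[4], d[3], act=act)
        self.sppf = SPPF(c[4], c[4])

        nd = max(round(2 * gd), 1)
        # top-down (FPN) path, extended to the stride-4 P2 level
        self.lat5 = ConvBnAct(c[4], c[3], 1, act=act)
        self.td4 = C3Mobile(2 * c[3], c[3], nd, act=act)
        self.lat4 = ConvBnAct(c[3], c[2], 1, act=act)
        self.td3 = C3Mobile(2 * c[2], c[2], nd, act=act)
        self.lat3 = ConvBnAct(c[2], c[1], 1, act=act)
        self.td2 = C3Mobile(2 * c[1], c[1], nd, act=act)
        self.up = nn.Upsample(2)

        # bottom-up (PAN) path
        self.bu2 = ConvBnAct(c[1], c[1], 3, 2, act=act)
        self.pan3 = C3Mobile(2 * c[1], c[2], nd, act=act)
        self.bu3 = ConvBnAct(c[2], c[2], 3, 2, act=act)
        self.pan4 = C3Mobile(2 * c[2], c[3], nd, act=act)
        self.bu4 = ConvBnAct(c[3], c[3], 3, 2, act=act)
        self.pan5 = C3Mobile(2 * c[3], c[4], nd, act=act)

        # heads: optional width reduction + MSSENet + prediction conv
        head_in = (c[1], c[2], c[3], c[4])
        cap = make_divisible(self.HEAD_WIDTH_CAP * gw, div)
        head_c = [min(ci, cap) for ci in head_in]
        self.head_reduce = ModuleList([
            ConvBnAct(ci, co, 1, act=act) if ci != co else nn.Identity()
            for ci, co in zip(head_in, head_c)])
        if cfg.head_attention == "mssenet":
            self.head_attn = ModuleList([
                MSSENet(co, reduction=_largest_divisor(co)) for co in head_c])
        else:
            self.head_attn = ModuleList([nn.Identity() for _ in head_c])
        self.detect = Detect(head_c, cfg.n_classes)

    def forward(self, x):
        x = self.stem(x)
        p2 = self.stage2(self.down2(x))
        p3 = self.stage3(self.down3(p2))
        p4 = self.stage4(self.down4(p3))
        p5 = self.sppf(self.stage5(self.down5(p4)))

        l5 = self.lat5(p5)
        t4 = self.td4(nn.concat([self.up(l5), p4], axis=1))
        l4 = self.lat4(t4)
        t3 = self.td3(nn.concat([self.up(l4), p3], axis=1))
        l3 = self.lat3(t3)
        t2 = self.td2(nn.concat([self.up(l3), p2], axis=1))

        m3 = self.pan3(nn.concat([self.bu2(t2), l3], axis=1))
        m4 = self.pan4(nn.concat([self.bu3(m3), l4], axis=1))
        m5 = self.pan5(nn.concat([self.bu4(m4), l5], axis=1))

        feats = [attn(red(f)) for red, attn, f in
                 zip(self.head_reduce, self.head_attn, (t2, m3, m4, m5))]
        return self.detect(feats)


class YOLOv5(Module):
    """Reference three-scale YOLOv5 (v6 layout); x-variant by default."""

    def __init__(self, n_classes: int = 80, depth_multiple: float = 1.33,
                 width_multiple: float = 1.25,
                 anchors: AnchorSet = YOLOV5_COCO_ANCHORS, seed: int = 0):
        super().__init__()
        nn.seed_rng(seed)
        self.anchor_set = anchors
        self.strides = (8, 16, 32)
        self.n_classes = n_classes

        def c(x):
            return make_divisible(x * width_multiple, 8)

        def d(n):
            return max(round(n * depth_multiple), 1)

        # backbone
        self.b0 = ConvBnAct(3, c(64), 6, 2, p=2)
        self.b1 = ConvBnAct(c(64), c(128), 3, 2)
        self.b2 = C3(c(128), c(128), d(3))
        self.b3 = ConvBnAct(c(128), c(256), 3, 2)
        self.b4 = C3(c(256), c(256), d(6))
        self.b5 = ConvBnAct(c(256), c(512), 3, 2)
        self.b6 = C3(c(512), c(512), d(9))
        self.b7 = ConvBnAct(c(512), c(1024), 3, 2)
        self.b8 = C3(c(1024), c(1024), d(3))
        self.b9 = SPPF(c(1024), c(1024))
        # head
        self.h10 = ConvBnAct(c(1024), c(512), 1)
        self.up = nn.Upsample(2)
        self.h13 = C3(c(1024), c(512), d(3), shortcut=False)
        self.h14 = ConvBnAct(c(512), c(256), 1)
        self.h17 = C3(c(512), c(256), d(3), shortcut=False)
        self.h18 = ConvBnAct(c(256), c(256), 3, 2)
        self.h20 = C3(c(512), c(512), d(3), shortcut=False)
        self.h21 = ConvBnAct(c(512), c(512), 3, 2)
        self.h23 = C3(c(1024), c(1024), d(3), shortcut=False)
        self.detect = Detect((c(256), c(512), c(1024)), n_classes)

    def forward(self, x):
        x = self.b1(self.b0(x))
        p3 = self.b4(self.b3(self.b2(x)))
        p4 = self.b6(self.b5(p3))
        p5 = self.b9(self.b8(self.b7(p4)))

        l5 = self.h10(p5)
        t4 = self.h13(nn.concat([self.up(l5), p4], axis=1))
        l4 = self.h14(t4)
        t3 = self.h17(nn.concat([self.up(l4), p3], axis=1))
        m4 = self.h20(nn.concat([self.h18(t3), l4], axis=1))
        m5 = self.h23(nn.concat([self.h21(m4), l5], axis=1))
        return self.detect([t3, m4, m5])


def build_blueberry_yolo(cfg: DetectorConfig | None = None, **kwargs) -> BlueberryYOLO:
    cfg = cfg if cfg is not None else DetectorConfig(**kwargs)
    return BlueberryYOLO(cfg)


def build_yolov5x(n_classes: int = 80, seed: int = 0) -> YOLOv5:
    """The published x-variant: depth 1.33, width 1.25, 80-class COCO head."""
    return YOLOv5(n_classes=n_classes, depth_multiple=1.33,
                  width_multiple=1.25, seed=seed)


# -- inference utilities -------------------------------------------------------

def decode_predictions(raw, anchor_set: AnchorSet, strides=None,
                       conf_thresh: float = 0.25, input_size: int | None = None):
    """Decode raw head maps to pixel-space detections.

    Per cell and anchor: centre = (2*sigmoid(txy) - 0.5 + grid) * stride,
    size = (2*sigmoid(twh))^2 * anchor, confidence = objectness * best
    class probability (all sigmoid).  Detections below ``conf_thresh`` are
    dropped; boxes are clipped to the input frame.
    """
    if not 0.0 <= conf_thresh <= 1.0:
        raise ValueError("conf_thresh must lie in [0, 1]")
    if len(raw) != anchor_set.n_levels:
        raise ValueError(f"{len(raw)} prediction levels vs "
                         f"{anchor_set.n_levels} anchor groups")
    na = anchor_set.per_scale
    out_batches = None
    for lvl, r in enumerate(raw):
        arr = r.data if isinstance(r, Tensor) else np.asarray(r)
        n, ch, h, w = arr.shape
        nc = ch // na - 5
        if input_size is not None and strides is None:
            stride = input_size // w
        else:
            stride = strides[lvl]
        if out_batches is None:
            out_batches = [[] for _ in range(n)]
        t = arr.reshape(n, na, 5 + nc, h, w)
        sig = _stable_sigmoid(t.astype(np.float64))
        gy, gx = np.mgrid[0:h, 0:w]
        cx = (sig[:, :, 0] * 2.0 - 0.5 + gx) * stride
        cy = (sig[:, :, 1] * 2.0 - 0.5 + gy) * stride
        pw = (sig[:, :, 2] * 2.0) ** 2 * anchor_set.anchors[lvl, :, 0][None, :, None, None]
        ph = (sig[:, :, 3] * 2.0) ** 2 * anchor_set.anchors[lvl, :, 1][None, :, None, None]
        obj = sig[:, :, 4]
        cls_prob = sig[:, :, 5:]
        best_cls = cls_prob.argmax(axis=2)
        best_prob = np.take_along_axis(cls_prob, best_cls[:, :, None], axis=2)[:, :, 0]
        conf = obj * best_prob
        size = input_size if input_size is not None else stride * w
        for b, a, j, i in zip(*np.nonzero(conf >= conf_thresh)):
            x1 = cx[b, a, j, i] - pw[b, a, j, i] / 2
            y1 = cy[b, a, j, i] - ph[b, a, j, i] / 2
            x2 = x1 + pw[b, a, j, i]
            y2 = y1 + ph[b, a, j, i]
            x1, y1 = max(x1, 0.0), max(y1, 0.0)
            x2, y2 = min(x2, float(size)), min(y2, float(size))
            if x2 <= x1 or y2 <= y1:
                continue
            out_batches[b].append(Detection(
                x1, y1, x2, y2, int(best_cls[b, a, j, i]),
                float(min(conf[b, a, j, i], 1.0))))
    return out_batches


def nms(detections, iou_thresh: float = 0.45):
    """Per-class greedy non-maximum suppression, highest confidence first."""
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must lie in (0, 1)")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    kept = []
    from .losses import iou as box_iou
    for i in order:
        d = detections[i]
        if all(k.class_id != d.class_id or box_iou(k, d) <= iou_thresh
               for k in kept):
            kept.append(d)
    return kept


def profile_model(model: Module, input_size: int):
    """(params in millions, forward GFLOPs at input_size, 2 FLOPs per MAC).

    FLOPs are counted by running the model's own forward pass on a shape
    shadow; conv and linear MACs are counted, BN/activation/pool are free.
    """
    params = model.param_count()
    shadow = Shadow((1, 3, input_size, input_size))
    model(shadow)
    gflops = 2.0 * shadow.counter["macs"] / 1e9
    return params / 1e6, gflops
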
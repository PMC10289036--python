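"""Bounding-box regression losses and the composite detection loss.

The box term is the EIoU loss

    L_EIOU = (1 - IoU) + rho^2(b, b_gt)/c^2 + (w - w_gt)^2/c_w^2 + (h - h_gt)^2/c_h^2

where c_w, c_h are the width and height of the minimum box enclosing the
prediction and the ground truth and c its diagonal.  Splitting the aspect
penalty into separate width and height terms (instead of CIoU's coupled
aspect-ratio term) gives a nonzero gradient whenever either side length is
wrong, which speeds convergence.  CIoU is kept as the comparison baseline.

All geometric math is written once over plain arrays *or* autodiff tensors
(the arithmetic operators and min/max dispatch on the operand type), so the
scalar API and the training loss share one code path.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Tensor, minimum, maximum
from .nn import functional as NF
from .voc import BoundingBox

__all__ = ["iou", "iou_xyxy_matrix", "eiou_loss", "ciou_loss",
           "eiou_center_size", "ciou_center_size", "iou_center_size",
           "assign_targets", "detection_loss"]

EPS = 1e-9


def _atan(x):
    return x.atan() if isinstance(x, Tensor) else np.arctan(x)


def _detach(x):
    return x.detach() if isinstance(x, Tensor) else x


# -- scalar/corner-form API ----------------------------------------------------

def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Standard intersection over union of two corner-form boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def iou_xyxy_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n,4) and (m,4) corner-form arrays."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ix = np.clip(np.minimum(a[:, None, 2], b[None, :, 2])
                 - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    iy = np.clip(np.minimum(a[:, None, 3], b[None, :, 3])
                 - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


# -- centre-size form, generic over arrays and tensors ------------------------

def iou_center_size(px, py, pw, ph, gx, gy, gw, gh):
    x1 = maximum(px - pw * 0.5, gx - gw * 0.5)
    x2 = minimum(px + pw * 0.5, gx + gw * 0.5)
    y1 = maximum(py - ph * 0.5, gy - gh * 0.5)
    y2 = minimum(py + ph * 0.5, gy + gh * 0.5)
    iw = maximum(x2 - x1, 0.0)
    ih = maximum(y2 - y1, 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    return inter / (union + EPS)


def _enclosing(px, py, pw, ph, gx, gy, gw, gh):
    cw = maximum(px + pw * 0.5, gx + gw * 0.5) - minimum(px - pw * 0.5, gx - gw * 0.5)
    ch = maximum(py + ph * 0.5, gy + gh * 0.5) - minimum(py - ph * 0.5, gy - gh * 0.5)
    return cw, ch


def eiou_center_size(px, py, pw, ph, gx, gy, gw, gh):
    """EIoU loss on centre-size boxes; zero iff the boxes coincide."""
    i = iou_center_size(px, py, pw, ph, gx, gy, gw, gh)
    cw, ch = _enclosing(px, py, pw, ph, gx, gy, gw, gh)
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    c2 = cw ** 2 + ch ** 2
    return ((1.0 - i)
            + rho2 / (c2 + EPS)
            + (pw - gw) ** 2 / (cw ** 2 + EPS)
            + (ph - gh) ** 2 / (ch ** 2 + EPS))


def ciou_center_size(px, py, pw, ph, gx, gy, gw, gh):
    """CIoU loss: (1 - IoU) + rho^2/c^2 + alpha * v (coupled aspect term)."""
    i = iou_center_size(px, py, pw, ph, gx, gy, gw, gh)
    cw, ch = _enclosing(px, py, pw, ph, gx, gy, gw, gh)
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    c2 = cw ** 2 + ch ** 2
    v = (4.0 / math.pi ** 2) * (_atan(gw / (gh + EPS)) - _atan(pw / (ph + EPS))) ** 2
    # alpha is the standard trade-off weight, treated as a constant in the gradient
    alpha = _detach(v) / (1.0 - _detach(i) + _detach(v) + EPS)
    return (1.0 - i) + rho2 / (c2 + EPS) + alpha * v


def _cs(box: BoundingBox):
    cx, cy = box.center
    return cx, cy, box.width, box.height


def eiou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    return float(eiou_center_size(*_cs(pred), *_cs(gt)))


def ciou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    return float(ciou_center_size(*_cs(pred), *_cs(gt)))


# -- target assignment and composite training loss -----------------------------

def assign_targets(annotations, anchor_set, strides, n_classes: int = 3,
                   ratio_thresh: float = 4.0, neighbor_cells: bool = True):
    """Assign ground-truth boxes to anchors and grid cells per level.

    An anchor at a level is a positive match for a box when the larger of
    the width and height ratios between box and anchor is below
    ``ratio_thresh`` (shape-ratio rule).  Matches land in the cell holding
    the box centre and, optionally, in the two adjacent cells nearest the
    centre (more positive samples for small objects).

    Returns, per level, a dict of integer index arrays (image, anchor, gj,
    gi), target boxes in grid units (gx, gy, gw, gh) and class ids.
    """
    n_levels = anchor_set.n_levels
    out = []
    for lvl in range(n_levels):
        rows = {k: [] for k in ("b", "a", "gj", "gi", "gx", "gy", "gw", "gh", "cls")}
        out.append(rows)
    for b_idx, ann in enumerate(annotations):
        for box in ann.boxes:
            cx, cy = box.center
            for lvl in range(n_levels):
                s = strides[lvl]
                anchors = anchor_set.anchors[lvl] / s  # grid units
                gw, gh = box.width / s, box.height / s
                gx, gy = cx / s, cy / s
                ratios = np.maximum.reduce([
                    gw / anchors[:, 0], anchors[:, 0] / gw,
                    gh / anchors[:, 1], anchors[:, 1] / gh])
                for a_idx in np.nonzero(ratios < ratio_thresh)[0]:
                    cells = [(int(gy), int(gx))]
                    if neighbor_cells:
                        fx, fy = gx - int(gx), gy - int(gy)
                        if fx < 0.5 and int(gx) > 0:
                            cells.append((int(gy), int(gx) - 1))
                        elif fx >= 0.5:
                            cells.append((int(gy), int(gx) + 1))
                        if fy < 0.5 and int(gy) > 0:
                            cells.append((int(gy) - 1, int(gx)))
                        elif fy >= 0.5:
                            cells.append((int(gy) + 1, int(gx)))
                    for gj, gi in cells:
                        rows = out[lvl]
                        rows["b"].append(b_idx)
                        rows["a"].append(int(a_idx))
                        rows["gj"].append(gj)
                        rows["gi"].append(gi)
                        rows["gx"].append(gx)
                        rows["gy"].append(gy)
                        rows["gw"].append(gw)
                        rows["gh"].append(gh)
                        rows["cls"].append(box.class_id)
    for rows in out:
        for k in rows:
            rows[k] = np.asarray(rows[k])
    return out


#: per-level objectness balance, finest grid first (4- and 3-level variants)
OBJ_BALANCE = {4: (4.0, 1.0, 0.4, 0.1), 3: (4.0, 1.0, 0.4)}


def detection_loss(raw_predictions, targets, anchor_set, strides,
                   n_classes: int = 3, weights=(0.05, 1.0, 0.5),
                   loss_kind: str = "eiou"):
    """Composite YOLO-style loss: weighted box + objectness + class terms.

    ``raw_predictions`` is the list of per-level head tensors of shape
    (N, anchors*(5+n_classes), h, w); ``targets`` comes from
    :func:`assign_targets`.  Returns (total, components dict).
    """
    box_fn = {"eiou": eiou_center_size, "ciou": ciou_center_size}[loss_kind]
    box_w, obj_w, cls_w = weights
    na = anchor_set.per_scale
    balance = OBJ_BALANCE.get(len(raw_predictions),
                              (1.0,) * len(raw_predictions))
    box_losses, obj_losses, cls_losses = [], [], []
    n_pos_total = 0
    for lvl, raw in enumerate(raw_predictions):
        n, _, h, w = raw.shape
        t = raw.reshape(n, na, 5 + n_classes, h, w)
        rows = targets[lvl]
        obj_target = np.zeros((n, na, h, w), dtype=np.float32)
        if len(rows["b"]):
            keep = (rows["gj"] >= 0) & (rows["gj"] < h) & \
                   (rows["gi"] >= 0) & (rows["gi"] < w)
            b, a = rows["b"][keep], rows["a"][keep]
            gj, gi = rows["gj"][keep], rows["gi"][keep]
            gx, gy = rows["gx"][keep], rows["gy"][keep]
            gw, gh = rows["gw"][keep], rows["gh"][keep]
            cls = rows["cls"][keep]
            n_pos = len(b)
            n_pos_total += n_pos
            if n_pos:
                anchors = anchor_set.anchors[lvl] / strides[lvl]
                aw, ah = anchors[a, 0], anchors[a, 1]
                tx = t[b, a, 0, gj, gi]
                ty = t[b, a, 1, gj, gi]
                tw = t[b, a, 2, gj, gi]
                th = t[b, a, 3, gj, gi]
                px = tx.sigmoid() * 2.0 - 0.5 + gi
                py = ty.sigmoid() * 2.0 - 0.5 + gj
                pw = (tw.sigmoid() * 2.0) ** 2 * aw
                ph = (th.sigmoid() * 2.0) ** 2 * ah
                box_vec = box_fn(px, py, pw, ph, gx, gy, gw, gh)
                box_losses.append(box_vec.mean())
                # objectness target: detached IoU of the decoded box
                iou_det = iou_center_size(
                    px.data, py.data, pw.data, ph.data, gx, gy, gw, gh)
                np.maximum.at(obj_target, (b, a, gj, gi),
                              np.clip(iou_det, 0.0, 1.0).astype(np.float32))
                onehot = np.zeros((n_pos, n_classes), dtype=np.float32)
                onehot[np.arange(n_pos), cls] = 1.0
                cls_terms = []
                for c in range(n_classes):
                    logits_c = t[b, a, 5 + c, gj, gi]
                    cls_terms.append(NF.bce_with_logits(logits_c, onehot[:, c]))
                cls_losses.append(sum(cls_terms) * (1.0 / n_classes))
        obj_logits = t[:, :, 4]
        obj_losses.append(NF.bce_with_logits(obj_logits, obj_target) * balance[lvl])

    zero = Tensor(np.float32(0.0))
    box_term = (sum(box_losses) * (1.0 / len(box_losses))) if box_losses else zero
    obj_term = sum(obj_losses) * (1.0 / len(obj_losses))
    cls_term = (sum(cls_losses) * (1.0 / len(cls_losses))) if cls_losses else zero
    total = box_term * box_w + obj_term * obj_w + cls_term * cls_w
    components = {"box": float(box_term.data), "obj": float(obj_term.data),
                  "cls": float(cls_term.data), "total": float(total.data),
                  "n_pos": n_pos_total}
    return total, components
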
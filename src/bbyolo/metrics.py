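"""Detection evaluation: P, R, per-class AP, mAP, FPS and stratum reports.

Definitions: P = TP/(TP+FP), R = TP/(FN+TP); AP is the area under the
precision-recall curve (all-point interpolation of the integral over
recall); mAP averages the APs of the N = 3 ripeness classes.  FPS = 1/t_avg
with t_avg the mean per-image inference wall time (reported for context —
it is hardware-bound and excluded from any correctness claim).

Matching is greedy in descending confidence: a detection is a true positive
when an unconsumed ground-truth box of the same class overlaps it with
IoU >= the threshold (default 0.5).
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .losses import iou_xyxy_matrix
from .models import decode_predictions, nms
from .voc import CLASS_NAMES, STRATA_VOCAB, read_voc_annotation

__all__ = ["EvalReport", "match_detections", "average_precision",
           "evaluate", "evaluate_detections", "interference_report"]


@dataclass
class EvalReport:
    per_class_ap: dict
    map: float
    precision: float
    recall: float
    fps: float
    counts: dict = field(default_factory=dict)
    per_stratum: dict | None = None

    def summary(self) -> str:
        lines = [f"{'class':<12}{'AP':>8}"]
        for name, ap in self.per_class_ap.items():
            lines.append(f"{name:<12}{ap:>8.4f}")
        lines.append(f"{'mAP':<12}{self.map:>8.4f}")
        lines.append(f"P={self.precision:.4f}  R={self.recall:.4f}  "
                     f"FPS={self.fps:.2f}  counts={self.counts}")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = {"per_class_ap": self.per_class_ap, "mAP": self.map,
             "precision": self.precision, "recall": self.recall,
             "fps": self.fps, "counts": self.counts}
        if self.per_stratum is not None:
            d["per_stratum"] = self.per_stratum
        return json.dumps(d, indent=2)


def match_detections(detections, ground_truths, iou_thresh: float = 0.5):
    """Greedy confidence-ordered matching within one image.

    Returns ``(tp, fp, fn, flags)`` where ``flags[i]`` is True iff the
    i-th detection (in descending-confidence order) is a true positive.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-(detections[i].confidence or 0.0), i))
    used = [False] * len(ground_truths)
    flags = []
    if ground_truths:
        gt_arr = np.array([g.as_xyxy() for g in ground_truths])
    for i in order:
        d = detections[i]
        best_iou, best_j = 0.0, -1
        if ground_truths:
            ious = iou_xyxy_matrix(d.as_xyxy()[None], gt_arr)[0]
            for j, g in enumerate(ground_truths):
                if used[j] or g.class_id != d.class_id:
                    continue
                if ious[j] >= iou_thresh and ious[j] > best_iou:
                    best_iou, best_j = ious[j], j
        if best_j >= 0:
            used[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    fp = len(flags) - tp
    fn = len(ground_truths) - tp
    return tp, fp, fn, flags


def average_precision(flags, n_gt: int) -> float:
    """AP from a ranked TP/FP flag list by all-point interpolation.

    The precision-recall curve is traced along the ranking; precision is
    replaced by its running maximum from the right (envelope) and the area
    under the resulting step function is integrated over recall.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    if n_gt == 0:
        return 0.0
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def _load_pairs(dataset):
    """Accept a DatasetManifest or an iterable of (image, AnnotatedImage)."""
    from .scenes import load_image
    if hasattr(dataset, "entries"):
        for e in dataset.entries:
            yield load_image(e.image_path), read_voc_annotation(e.annotation_path)
    else:
        yield from dataset


def _infer(model, image, conf_thresh, nms_iou):
    from .nn import Tensor, no_grad
    x = np.transpose(image.astype(np.float32) / 255.0, (2, 0, 1))[None]
    was_training = model.training
    model.eval()
    with no_grad():
        raw = model(Tensor(x))
    if was_training:
        model.train()
    dets = decode_predictions(raw, model.anchor_set, strides=model.strides,
                              conf_thresh=conf_thresh,
                              input_size=image.shape[0])[0]
    return nms(dets, nms_iou)


def evaluate_detections(per_image, iou_thresh: float = 0.5,
                        n_classes: int = 3, elapsed: float | None = None
                        ) -> EvalReport:
    """Score pre-computed (detections, ground_truths) pairs.

    ``per_image`` is a list of (list of Detection, list of BoundingBox).
    AP ranks each class's detections across all images by confidence; P and
    R are micro-averaged over classes at the operating threshold.
    """
    scored = {c: [] for c in range(n_classes)}  # (confidence, is_tp)
    n_gt = {c: 0 for c in range(n_classes)}
    tp = fp = fn = 0
    for dets, gts in per_image:
        for c in range(n_classes):
            dc = [d for d in dets if d.class_id == c]
            gc = [g for g in gts if g.class_id == c]
            n_gt[c] += len(gc)
            tpc, fpc, fnc, flags = match_detections(dc, gc, iou_thresh)
            tp, fp, fn = tp + tpc, fp + fpc, fn + fnc
            confs = sorted((d.confidence for d in dc), reverse=True)
            scored[c].extend(zip(confs, flags))
    per_class_ap = {}
    for c in range(n_classes):
        ranked = sorted(scored[c], key=lambda t: -t[0])
        per_class_ap[CLASS_NAMES[c]] = average_precision(
            [f for _, f in ranked], n_gt[c])
    m_ap = float(np.mean(list(per_class_ap.values())))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (fn + tp) if fn + tp else 0.0
    n_img = max(len(per_image), 1)
    fps = n_img / elapsed if elapsed else 0.0
    return EvalReport(per_class_ap, m_ap, precision, recall, fps,
                      {"TP": tp, "FP": fp, "FN": fn})


def evaluate(model_or_dets, dataset, iou_thresh: float = 0.5,
             conf_thresh: float = 0.25, nms_iou: float = 0.45,
             n_classes: int = 3) -> EvalReport:
    """Run a model over a dataset (or score given detections) into an EvalReport.

    ``model_or_dets`` is either a detector module or a per-image list of
    detection lists aligned with the dataset order.
    """
    pairs = list(_load_pairs(dataset))
    if not pairs:
        raise ValueError("empty dataset")
    per_image = []
    elapsed = None
    if hasattr(model_or_dets, "forward"):
        t0 = time.perf_counter()
        for img, ann in pairs:
            dets = _infer(model_or_dets, img, conf_thresh, nms_iou)
            per_image.append((dets, ann.boxes))
        elapsed = time.perf_counter() - t0
    else:
        if len(model_or_dets) != len(pairs):
            raise ValueError("detections/images length mismatch")
        for dets, (_, ann) in zip(model_or_dets, pairs):
            per_image.append((dets, ann.boxes))
    return evaluate_detections(per_image, iou_thresh, n_classes, elapsed)


def interference_report(model, datasets_by_stratum: dict,
                        iou_thresh: float = 0.5, conf_thresh: float = 0.25,
                        csv_path=None, json_path=None) -> dict:
    """Per-stratum mAP table over the 3 factors x 3 levels vocabulary.

    ``datasets_by_stratum`` maps (factor, level) — e.g. ("fruit_density",
    "tightly_arranged") — to a dataset.  Missing strata are reported as
    None, never as zero.  Returns {factor: {level: mAP | None}} and
    optionally writes CSV / plot-ready JSON.
    """
    table = {}
    for factor, levels in STRATA_VOCAB.items():
        table[factor] = {}
        for level in levels:
            ds = datasets_by_stratum.get((factor, level))
            if ds is None:
                table[factor][level] = None
                continue
            rep = evaluate(model, ds, iou_thresh, conf_thresh)
            table[factor][level] = rep.map
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["factor", "level", "mAP"])
            for factor, levels in table.items():
                for level, value in levels.items():
                    writer.writerow([factor, level,
                                     "" if value is None else f"{value:.4f}"])
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(table, fh, indent=2)
    return table
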
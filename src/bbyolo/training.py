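"""Toy-scale training loop for the detector on CPU.

The recipe follows the reference protocol — stochastic gradient descent,
initial learning rate 0.001, weight decay 0.0005 — with sizes chosen for a
single CPU: small images, a slim width multiple, tens of epochs.  The loop
records per-component losses per epoch (box / objectness / class) and keeps
the checkpoint with the best validation mAP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .losses import assign_targets, detection_loss, iou_xyxy_matrix
from .metrics import evaluate, _infer, _load_pairs
from .nn import Tensor

__all__ = ["TrainConfig", "SGD", "train", "mean_matched_iou"]


@dataclass
class TrainConfig:
    initial_lr: float = 0.001
    weight_decay: float = 0.0005
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    loss: str = "eiou"
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    final_lr_fraction: float = 0.1
    eval_conf_thresh: float = 0.1

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("eiou", "ciou"):
            raise ValueError(f"unknown loss {self.loss!r}")


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay.

    Weight decay is applied only to convolution/linear weights (ndim >= 2),
    not to normalisation parameters or biases.
    """

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim >= 2:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data = p.data + v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _to_batch(images):
    arr = np.stack([np.transpose(im.astype(np.float32) / 255.0, (2, 0, 1))
                    for im in images])
    return Tensor(arr)


def train(model, train_data, val_data, cfg: TrainConfig):
    """Train a detector; returns (best_state_dict, history).

    ``train_data``/``val_data`` are DatasetManifests or in-memory lists of
    (image, AnnotatedImage) pairs.  History rows carry the per-component
    training losses and the validation mAP of each epoch.  Aborts with a
    diagnostic on non-finite loss.
    """
    train_pairs = list(_load_pairs(train_data))
    val_pairs = list(_load_pairs(val_data))
    if not train_pairs or not val_pairs:
        raise ValueError("datasets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.initial_lr, cfg.momentum, cfg.weight_decay)
    history = []
    best = {"map": -1.0, "state": None, "epoch": -1}
    n = len(train_pairs)
    weights = (cfg.box_weight, cfg.obj_weight, cfg.cls_weight)
    for epoch in range(cfg.epochs):
        # cosine decay of the learning rate
        t = epoch / max(cfg.epochs - 1, 1)
        opt.lr = cfg.initial_lr * (cfg.final_lr_fraction
                                   + (1 - cfg.final_lr_fraction)
                                   * 0.5 * (1 + math.cos(math.pi * t)))
        model.train()
        order = rng.permutation(n)
        sums = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            images = [train_pairs[i][0] for i in idx]
            anns = [train_pairs[i][1] for i in idx]
            x = _to_batch(images)
            raw = model(x)
            targets = assign_targets(anns, model.anchor_set, model.strides,
                                     model.n_classes)
            loss, comps = detection_loss(raw, targets, model.anchor_set,
                                         model.strides, model.n_classes,
                                         weights=weights, loss_kind=cfg.loss)
            if not np.isfinite(comps["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={comps['total']}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in sums:
                sums[k] += comps[k]
            n_batches += 1
        row = {k: v / n_batches for k, v in sums.items()}
        report = evaluate(model, val_pairs, conf_thresh=cfg.eval_conf_thresh)
        row.update({"epoch": epoch, "val_map": report.map, "lr": opt.lr})
        history.append(row)
        if report.map > best["map"]:
            best = {"map": report.map, "epoch": epoch,
                    "state": {k: v.copy() for k, v in model.state_dict().items()}}
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return best, history


def mean_matched_iou(model, dataset, conf_thresh: float = 0.1,
                     nms_iou: float = 0.45) -> float:
    """Mean over ground-truth boxes of the best same-class detection IoU.

    An undetected ground truth contributes zero, so the statistic rewards
    both localisation quality and coverage.
    """
    pairs = list(_load_pairs(dataset))
    vals = []
    for img, ann in pairs:
        dets = _infer(model, img, conf_thresh, nms_iou)
        for g in ann.boxes:
            same = [d for d in dets if d.class_id == g.class_id]
            if not same:
                vals.append(0.0)
                continue
            ious = iou_xyxy_matrix(g.as_xyxy()[None],
                                   np.array([d.as_xyxy() for d in same]))[0]
            vals.append(float(ious.max()))
    return float(np.mean(vals)) if vals else 0.0
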
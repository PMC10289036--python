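"""Box-regression losses: hand-checked values, invariants, composite loss."""

import math

import numpy as np
import pytest

from bbyolo.anchors import AnchorSet
from bbyolo.losses import (assign_targets, ciou_loss, detection_loss,
                           eiou_center_size, eiou_loss, iou, iou_center_size)
from bbyolo.nn import Tensor
from bbyolo.voc import AnnotatedImage, BoundingBox

RNG = np.random.default_rng(9)


def random_box(rng, lo=0.0, hi=80.0):
    x0, y0 = rng.uniform(lo, hi, 2)
    return BoundingBox(x0, y0, x0 + rng.uniform(1, 40), y0 + rng.uniform(1, 40),
                       int(rng.integers(3)))


def test_iou_hand_cases():
    a = BoundingBox(0, 0, 10, 10, 0)
    assert iou(a, a) == 1.0
    assert iou(a, BoundingBox(20, 20, 30, 30, 0)) == 0.0
    assert iou(BoundingBox(-1, -1, 1, 1, 0), BoundingBox(0, 0, 2, 2, 0)) \
        == pytest.approx(1 / 7)


def test_eiou_hand_evaluated_terms():
    pred = BoundingBox(-1, -1, 1, 1, 0)   # centre (0,0), w = h = 2
    gt = BoundingBox(0, 0, 2, 2, 0)       # centre (1,1), w = h = 2
    # 1 - 1/7  +  (1^2+1^2)/(3^2+3^2)  +  0  +  0
    assert eiou_loss(pred, gt) == pytest.approx(6 / 7 + 1 / 9, abs=1e-6)
    assert eiou_loss(pred, pred) == pytest.approx(0.0, abs=1e-6)


def test_ciou_term_by_term_oracle():
    pred = BoundingBox(0, 0, 4, 2, 0)
    gt = BoundingBox(1, 1, 7, 5, 0)
    i = iou(pred, gt)
    rho2 = (2 - 4) ** 2 + (1 - 3) ** 2
    c2 = 7 ** 2 + 5 ** 2
    v = 4 / math.pi ** 2 * (math.atan(6 / 4) - math.atan(4 / 2)) ** 2
    alpha = v / (1 - i + v)
    assert ciou_loss(pred, gt) == pytest.approx((1 - i) + rho2 / c2 + alpha * v,
                                                abs=1e-6)
    assert ciou_loss(pred, pred) == pytest.approx(0.0, abs=1e-6)


def test_eiou_swap_symmetry_and_translation_invariance():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b = random_box(rng), random_box(rng)
        assert eiou_loss(a, b) == pytest.approx(eiou_loss(b, a), rel=1e-9)
        dx, dy = rng.uniform(-50, 50, 2)
        a2 = BoundingBox(a.x_min + dx, a.y_min + dy, a.x_max + dx, a.y_max + dy,
                         a.class_id)
        b2 = BoundingBox(b.x_min + dx, b.y_min + dy, b.x_max + dx, b.y_max + dy,
                         b.class_id)
        assert eiou_loss(a2, b2) == pytest.approx(eiou_loss(a, b), rel=1e-6)
        assert eiou_loss(a, b) >= (1 - iou(a, b)) - 1e-12  # penalties non-negative


def test_eiou_decreases_along_shrinking_offset_path():
    gt = BoundingBox(0, 0, 10, 10, 0)
    losses = []
    for f in np.linspace(1.0, 0.0, 11):
        pred = BoundingBox(8 * f, 8 * f, 10 + 8 * f, 10 + 8 * f, 0)
        losses.append(eiou_loss(pred, gt))
    assert all(l1 > l2 for l1, l2 in zip(losses, losses[1:]))


def test_equal_size_boxes_reduce_both_losses_to_diou():
    rng = np.random.default_rng(1)
    for _ in range(100):
        w, h = rng.uniform(2, 30, 2)
        x0, y0 = rng.uniform(0, 40, 2)
        x1, y1 = rng.uniform(0, 40, 2)
        a = BoundingBox(x0, y0, x0 + w, y0 + h, 0)
        b = BoundingBox(x1, y1, x1 + w, y1 + h, 0)
        diou = (1 - iou(a, b)) + (
            ((x0 - x1) ** 2 + (y0 - y1) ** 2)
            / ((abs(x0 - x1) + w) ** 2 + (abs(y0 - y1) + h) ** 2))
        assert ciou_loss(a, b) == pytest.approx(diou, abs=1e-6)  # v = 0
        assert eiou_loss(a, b) == pytest.approx(diou, abs=1e-6)  # wh terms = 0


def test_eiou_gradient_nonzero_off_optimum():
    """No plateau: the box term pushes back whenever pred != gt."""
    rng = np.random.default_rng(2)
    for _ in range(100):
        gx, gy = rng.uniform(10, 50, 2)
        gw, gh = rng.uniform(4, 30, 2)
        params = Tensor(np.array([gx + rng.uniform(-20, 20),
                                  gy + rng.uniform(-20, 20),
                                  gw * rng.uniform(0.3, 3.0),
                                  gh * rng.uniform(0.3, 3.0)]),
                        requires_grad=True)
        if np.allclose(params.data, [gx, gy, gw, gh]):
            continue
        loss = eiou_center_size(params[np.array([0])], params[np.array([1])],
                                params[np.array([2])], params[np.array([3])],
                                gx, gy, gw, gh)
        loss.sum().backward()
        assert np.abs(params.grad).max() > 1e-8


TOY_ANCHORS = AnchorSet(np.array([
    [[8, 8], [10, 12], [12, 10]],
    [[16, 16], [20, 24], [24, 20]],
    [[32, 32], [40, 48], [48, 40]],
    [[64, 64], [80, 96], [96, 80]],
], dtype=float), (16, 8, 4, 2))
STRIDES = (4, 8, 16, 32)


def _perfect_raw(ann, n=1):
    """Raw logits that decode exactly onto the (anchor-sized) target boxes."""
    shapes = [(n, 24, 16, 16), (n, 24, 8, 8), (n, 24, 4, 4), (n, 24, 2, 2)]
    raw = [np.full(s, -20.0, np.float32) for s in shapes]
    targets = assign_targets([ann], TOY_ANCHORS, STRIDES, neighbor_cells=False)
    logit = lambda p: math.log(p / (1 - p))
    for lvl, rows in enumerate(targets):
        t = raw[lvl].reshape(n, 3, 8, *raw[lvl].shape[2:])
        anchors = TOY_ANCHORS.anchors[lvl] / STRIDES[lvl]
        for b, a, gj, gi, gx, gy, gw, gh, cls in zip(*rows.values()):
            t[b, a, 0, gj, gi] = logit((gx - gi + 0.5) / 2)
            t[b, a, 1, gj, gi] = logit((gy - gj + 0.5) / 2)
            t[b, a, 2, gj, gi] = logit(math.sqrt(gw / anchors[a, 0]) / 2)
            t[b, a, 3, gj, gi] = logit(math.sqrt(gh / anchors[a, 1]) / 2)
            t[b, a, 4, gj, gi] = 20.0
            t[b, a, 5 + cls, gj, gi] = 20.0
    return [Tensor(r) for r in raw]


def test_detection_loss_perfect_predictions_have_zero_box_term():
    ann = AnnotatedImage("a", 64, 64, [BoundingBox(12, 12, 28, 28, 1),
                                       BoundingBox(40, 44, 56, 60, 0)])
    raw = _perfect_raw(ann)
    targets = assign_targets([ann], TOY_ANCHORS, STRIDES, neighbor_cells=False)
    total, comps = detection_loss(raw, targets, TOY_ANCHORS, STRIDES)
    assert comps["box"] == pytest.approx(0.0, abs=1e-6)
    assert comps["cls"] == pytest.approx(0.0, abs=1e-6)
    assert comps["n_pos"] > 0


def test_detection_loss_swapping_box_criterion_changes_only_box_term():
    ann = AnnotatedImage("a", 64, 64, [BoundingBox(10, 10, 30, 34, 2)])
    raw = [Tensor(RNG.normal(0, 1, s).astype(np.float32))
           for s in [(1, 24, 16, 16), (1, 24, 8, 8), (1, 24, 4, 4), (1, 24, 2, 2)]]
    targets = assign_targets([ann], TOY_ANCHORS, STRIDES)
    _, eiou_comps = detection_loss(raw, targets, TOY_ANCHORS, STRIDES,
                                   loss_kind="eiou")
    _, ciou_comps = detection_loss(raw, targets, TOY_ANCHORS, STRIDES,
                                   loss_kind="ciou")
    assert eiou_comps["obj"] == pytest.approx(ciou_comps["obj"], rel=1e-9)
    assert eiou_comps["cls"] == pytest.approx(ciou_comps["cls"], rel=1e-9)
    assert eiou_comps["box"] != pytest.approx(ciou_comps["box"], rel=1e-3)


def test_detection_loss_no_targets_defines_obj_term():
    ann = AnnotatedImage("empty", 64, 64, [])
    raw = [Tensor(RNG.normal(0, 1, s).astype(np.float32))
           for s in [(1, 24, 16, 16), (1, 24, 8, 8), (1, 24, 4, 4), (1, 24, 2, 2)]]
    targets = assign_targets([ann], TOY_ANCHORS, STRIDES)
    total, comps = detection_loss(raw, targets, TOY_ANCHORS, STRIDES)
    assert comps["box"] == 0.0 and comps["cls"] == 0.0
    assert comps["obj"] > 0.0 and np.isfinite(comps["total"])


def test_assign_targets_shape_ratio_rule():
    # a 12x12 box: compatible with 8..24-px anchors (ratio < 4) but not 64+
    ann = AnnotatedImage("a", 64, 64, [BoundingBox(20, 20, 32, 32, 0)])
    targets = assign_targets([ann], TOY_ANCHORS, STRIDES, neighbor_cells=False)
    assert len(targets[0]["b"]) > 0
    assert len(targets[3]["b"]) == 0
    for lvl, rows in enumerate(targets):
        for a_idx, gw, gh in zip(rows["a"], rows["gw"], rows["gh"]):
            aw, ah = TOY_ANCHORS.anchors[lvl, a_idx] / STRIDES[lvl]
            assert max(gw / aw, aw / gw, gh / ah, ah / gh) < 4.0
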
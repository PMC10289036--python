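"""Detector assembly: profiles, output shapes, decoding and NMS."""

import itertools

import numpy as np
import pytest

from bbyolo.anchors import AnchorSet, cluster_anchors
from bbyolo.losses import iou, iou_xyxy_matrix
from bbyolo.models import (DetectorConfig, build_blueberry_yolo, build_yolov5x,
                           decode_predictions, nms, profile_model)
from bbyolo.nn import Conv2d, Shadow, Tensor
from bbyolo.voc import Detection

RNG = np.random.default_rng(3)

TOY_ANCHORS = AnchorSet(np.array([
    [[8, 8], [10, 12], [12, 10]],
    [[16, 16], [20, 24], [24, 20]],
    [[32, 32], [40, 48], [48, 40]],
    [[64, 64], [80, 96], [96, 80]],
], dtype=float), (16, 8, 4, 2))


@pytest.fixture(scope="module")
def yolov5x():
    return build_yolov5x()


@pytest.fixture(scope="module")
def blueberry():
    return build_blueberry_yolo(DetectorConfig())


def tiny(seed=0):
    return build_blueberry_yolo(DetectorConfig(
        input_size=64, anchors=TOY_ANCHORS, width_multiple=0.125,
        depth_multiple=0.34, seed=seed))


def test_yolov5x_profile_matches_published_figures(yolov5x):
    params_m, gflops = profile_model(yolov5x, 640)
    assert round(params_m, 1) == 86.7
    assert abs(gflops - 205.7) / 205.7 < 0.01


def test_yolov5x_three_scales_at_strides_8_16_32(yolov5x):
    outs = yolov5x(Shadow((1, 3, 640, 640)))
    assert [o.shape for o in outs] == [
        (1, 3 * 85, 80, 80), (1, 3 * 85, 40, 40), (1, 3 * 85, 20, 20)]


def test_blueberry_grids_and_parameter_budget(yolov5x, blueberry):
    outs = blueberry(Shadow((1, 3, 608, 608)))
    assert [o.shape[-1] for o in outs] == [152, 76, 38, 19]
    assert all(o.shape[1] == 3 * 8 for o in outs)
    params_m, _ = profile_model(blueberry, 608)
    assert abs(params_m - 13.1) / 13.1 <= 0.20
    assert blueberry.param_count() < yolov5x.param_count()


def test_blueberry_forward_shapes_tiny():
    model = tiny().eval()
    outs = model(Tensor(RNG.normal(size=(2, 3, 64, 64)).astype(np.float32)))
    assert [o.shape for o in outs] == [
        (2, 24, 16, 16), (2, 24, 8, 8), (2, 24, 4, 4), (2, 24, 2, 2)]
    assert all(np.all(np.isfinite(o.data)) for o in outs)


def test_anchor_level_mismatch_rejected():
    three_level = AnchorSet(TOY_ANCHORS.anchors[:3], (16, 8, 4))
    with pytest.raises(ValueError):
        build_blueberry_yolo(DetectorConfig(anchors=three_level))
    with pytest.raises(ValueError):
        DetectorConfig(input_size=100)


def test_profile_hand_count_and_scaling_laws():
    conv = Conv2d(2, 1, 7, bias=False)
    assert conv.param_count() == 98
    model = tiny()
    p1, g1 = profile_model(model, 64)
    p2, g2 = profile_model(model, 128)
    assert p1 == p2                      # params independent of input size
    assert abs(g2 / g1 - 4.0) < 0.05     # FLOPs scale with input area


def _raw_levels(fill=-20.0):
    shapes = [(1, 24, 16, 16), (1, 24, 8, 8), (1, 24, 4, 4), (1, 24, 2, 2)]
    return [np.full(s, fill, np.float32) for s in shapes]


def test_decode_empty_on_low_logits():
    dets = decode_predictions(_raw_levels(), TOY_ANCHORS, strides=(4, 8, 16, 32),
                              conf_thresh=0.25, input_size=64)
    assert dets == [[]]


def test_decode_single_cell_hand_computed():
    raw = _raw_levels()
    # level 1 (stride 8), anchor 0 = (16,16), cell (gj=3, gi=2)
    t = raw[1].reshape(1, 3, 8, 8, 8)
    t[0, 0, 0, 3, 2] = 0.0    # sigmoid 0.5 -> dx = 2*0.5-0.5 = 0.5 (cell centre)
    t[0, 0, 1, 3, 2] = 0.0
    t[0, 0, 2, 3, 2] = 0.0    # pw = (2*0.5)^2 * 16 = 16
    t[0, 0, 3, 3, 2] = 0.0
    t[0, 0, 4, 3, 2] = 8.0    # objectness ~ 1
    t[0, 0, 5, 3, 2] = 8.0    # class 0
    dets = decode_predictions(raw, TOY_ANCHORS, strides=(4, 8, 16, 32),
                              conf_thresh=0.25, input_size=64)[0]
    assert len(dets) == 1
    d = dets[0]
    cx, cy = (d.x_min + d.x_max) / 2, (d.y_min + d.y_max) / 2
    assert (cx, cy) == pytest.approx((2.5 * 8, 3.5 * 8), abs=1e-3)
    assert (d.width, d.height) == pytest.approx((16, 16), abs=1e-3)
    assert d.class_id == 0 and d.confidence > 0.99


def test_decode_monotone_in_confidence_threshold():
    raw = [RNG.normal(0, 3, s).astype(np.float32)
           for s in [(1, 24, 16, 16), (1, 24, 8, 8), (1, 24, 4, 4), (1, 24, 2, 2)]]
    counts = [len(decode_predictions(raw, TOY_ANCHORS, strides=(4, 8, 16, 32),
                                     conf_thresh=t, input_size=64)[0])
              for t in (0.05, 0.25, 0.5, 0.9)]
    assert counts == sorted(counts, reverse=True)
    with pytest.raises(ValueError):
        decode_predictions(raw, TOY_ANCHORS, strides=(4, 8, 16, 32), conf_thresh=1.5)


def brute_force_nms(dets, thresh):
    """Keep a detection iff no higher-priority same-class kept box overlaps it."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept = []
    for i in order:
        if all(dets[j].class_id != dets[i].class_id
               or iou(dets[j], dets[i]) <= thresh for j in kept):
            kept.append(i)
    return [dets[i] for i in kept]


def test_nms_basics():
    d = Detection(0, 0, 10, 10, 0, 0.9)
    assert nms([d]) == [d]
    d2 = Detection(0, 0, 10, 10, 0, 0.8)
    assert nms([d, d2], 0.45) == [d]
    other_class = Detection(0, 0, 10, 10, 1, 0.8)
    assert nms([d, other_class], 0.45) == [d, other_class]
    with pytest.raises(ValueError):
        nms([d], 0.0)


def test_nms_matches_brute_force_on_random_instances():
    for trial in range(40):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 11))
        dets = []
        for _ in range(n):
            x0, y0 = rng.uniform(0, 60, 2)
            dets.append(Detection(x0, y0, x0 + rng.uniform(5, 40),
                                  y0 + rng.uniform(5, 40),
                                  int(rng.integers(2)), float(rng.uniform(0.1, 1))))
        for thresh in (0.3, 0.5, 0.7):
            assert nms(dets, thresh) == brute_force_nms(dets, thresh)


def test_cluster_anchors_feed_models_end_to_end(rng):
    boxes = rng.uniform(5, 30, (40, 2))
    anchors = cluster_anchors(boxes, k=12, seed=0, grids=(16, 8, 4, 2))
    model = build_blueberry_yolo(DetectorConfig(
        input_size=64, anchors=anchors, width_multiple=0.125,
        depth_multiple=0.34))
    outs = model(Shadow((1, 3, 64, 64)))
    assert [o.shape[-1] for o in outs] == [16, 8, 4, 2]
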
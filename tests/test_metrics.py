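"""Evaluation suite: matching, AP integration, reports."""

import itertools

import numpy as np
import pytest

from bbyolo.metrics import (average_precision, evaluate, evaluate_detections,
                            interference_report, match_detections)
from bbyolo.voc import BoundingBox, Detection


def det(x0, y0, x1, y1, cls, conf):
    return Detection(x0, y0, x1, y1, cls, conf)


def gt(x0, y0, x1, y1, cls):
    return BoundingBox(x0, y0, x1, y1, cls)


def test_match_perfect_and_empty():
    gts = [gt(0, 0, 10, 10, 0), gt(20, 20, 40, 40, 1)]
    dets = [det(0, 0, 10, 10, 0, 0.9), det(20, 20, 40, 40, 1, 0.8)]
    assert match_detections(dets, gts, 0.5)[:3] == (2, 0, 0)
    assert match_detections([], gts, 0.5)[:3] == (0, 0, 2)
    assert match_detections(dets, [], 0.5)[:3] == (0, 2, 0)


def test_match_constructed_tp_fp_tp_ordering():
    gts = [gt(0, 0, 10, 10, 0), gt(30, 30, 42, 44, 0)]
    dets = [
        det(0, 0, 10, 10, 0, 0.9),     # TP on first gt
        det(60, 60, 70, 70, 0, 0.8),   # FP (no overlap)
        det(31, 31, 42, 44, 0, 0.7),   # TP on second gt
    ]
    tp, fp, fn, flags = match_detections(dets, gts, 0.5)
    assert (tp, fp, fn) == (2, 1, 0)
    assert flags == [True, False, True]


def test_match_consumes_each_gt_once_and_requires_class():
    gts = [gt(0, 0, 10, 10, 0)]
    dets = [det(0, 0, 10, 10, 0, 0.9), det(0, 0, 10, 10, 0, 0.8)]
    assert match_detections(dets, gts, 0.5)[:3] == (1, 1, 0)
    wrong_class = [det(0, 0, 10, 10, 1, 0.9)]
    assert match_detections(wrong_class, gts, 0.5)[:3] == (0, 1, 1)


def brute_force_ap(flags, n_gt, grid=200_000):
    """Rectangle-sum integration of the interpolated precision envelope."""
    flags = np.asarray(flags, bool)
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = np.concatenate([[0.0], tp / n_gt])
    precision = np.concatenate([[1.0], tp / (tp + fp)])
    rs = (np.arange(grid) + 0.5) / grid
    # interpolated precision at each sampled recall: max precision at recall >= r
    reachable = recall[None, :] >= rs[:, None]
    ps = np.where(reachable, precision[None, :], 0.0).max(axis=1)
    return ps.mean()  # integral over [0, 1]


def test_ap_hand_case_and_trivial_cases():
    assert average_precision([True, True], 2) == 1.0
    assert average_precision([True, False, True], 2) == pytest.approx(
        0.5 * 1.0 + 0.5 * (2 / 3))
    assert average_precision([], 5) == 0.0
    assert average_precision([False, True], 0) == 0.0  # defined as 0
    with pytest.raises(ValueError):
        average_precision([True], -1)


def test_ap_matches_brute_force_on_all_short_rankings():
    """Exhaustive TP/FP patterns up to length 8 (plus spot checks to 12)."""
    for length in range(1, 9):
        for pattern in itertools.product([True, False], repeat=length):
            n_tp = sum(pattern)
            for n_gt in {max(n_tp, 1), n_tp + 2}:
                got = average_precision(list(pattern), n_gt)
                want = brute_force_ap(pattern, n_gt, grid=20_000)
                assert abs(got - want) < 1e-3, (pattern, n_gt)
    rng = np.random.default_rng(0)
    for _ in range(20):
        pattern = rng.random(12) < 0.6
        n_gt = int(pattern.sum() + rng.integers(0, 4)) or 1
        assert abs(average_precision(pattern, n_gt)
                   - brute_force_ap(pattern, n_gt)) < 1e-4


def test_ap_never_raised_by_trailing_false_positives():
    base = [True, False, True]
    ap0 = average_precision(base, 2)  # recall already 1.0
    for extra in range(1, 5):
        assert average_precision(base + [False] * extra, 2) <= ap0 + 1e-12


def test_evaluate_perfect_detections():
    per_image = []
    rng = np.random.default_rng(4)
    for _ in range(5):
        gts = []
        for c in range(3):
            x0, y0 = rng.uniform(0, 50, 2)
            gts.append(gt(x0, y0, x0 + 10, y0 + 10, c))
        dets = [det(g.x_min, g.y_min, g.x_max, g.y_max, g.class_id, 0.9)
                for g in gts]
        per_image.append((dets, gts))
    rep = evaluate_detections(per_image)
    assert rep.map == rep.precision == rep.recall == 1.0
    assert rep.counts == {"TP": 15, "FP": 0, "FN": 0}


def test_missing_class_caps_map_at_two_thirds():
    gts = [gt(0, 0, 10, 10, 0), gt(20, 20, 30, 30, 1), gt(40, 40, 50, 50, 2)]
    dets = [det(0, 0, 10, 10, 0, 0.9), det(20, 20, 30, 30, 1, 0.9)]
    rep = evaluate_detections([(dets, gts)])
    assert rep.per_class_ap["unripe"] == 0.0
    assert rep.map <= 2 / 3 + 1e-12


def hand_reference_evaluator(per_image, iou_thresh=0.5):
    """Independent AP/mAP implementation: explicit loops, no shared code paths."""
    aps = []
    for c in range(3):
        records = []  # (conf, image index, det)
        n_gt = 0
        for i, (dets, gts) in enumerate(per_image):
            n_gt += sum(g.class_id == c for g in gts)
            records += [(d.confidence, i, d) for d in dets if d.class_id == c]
        records.sort(key=lambda r: -r[0])
        consumed = {}
        flags = []
        for conf, i, d in records:
            gts_c = [g for g in per_image[i][1] if g.class_id == c]
            best, best_j = 0.0, None
            for j, g in enumerate(gts_c):
                if (i, j) in consumed:
                    continue
                ix = max(0, min(d.x_max, g.x_max) - max(d.x_min, g.x_min))
                iy = max(0, min(d.y_max, g.y_max) - max(d.y_min, g.y_min))
                ov = ix * iy / (d.area + g.area - ix * iy)
                if ov >= iou_thresh and ov > best:
                    best, best_j = ov, j
            if best_j is not None:
                consumed[(i, best_j)] = True
                flags.append(True)
            else:
                flags.append(False)
        # trapezoid-free envelope integration, written independently
        ap = 0.0
        tp = fp = 0
        pr = [(0.0, 1.0)]
        for f in flags:
            tp, fp = tp + f, fp + (not f)
            pr.append((tp / n_gt if n_gt else 0.0, tp / (tp + fp)))
        prev_r = 0.0
        for k, (r, _) in enumerate(pr):
            if r > prev_r:
                ap += (r - prev_r) * max(p for rr, p in pr[k:])
                prev_r = r
        aps.append(ap if n_gt else 0.0)
    return float(np.mean(aps))


def test_evaluate_matches_independent_reference_on_fixture():
    rng = np.random.default_rng(7)
    per_image = []
    for _ in range(6):
        gts, dets = [], []
        for _ in range(rng.integers(1, 5)):
            x0, y0 = rng.uniform(0, 50, 2)
            g = gt(x0, y0, x0 + rng.uniform(8, 20), y0 + rng.uniform(8, 20),
                   int(rng.integers(3)))
            gts.append(g)
            if rng.random() < 0.8:  # jittered detection
                dx, dy = rng.uniform(-3, 3, 2)
                dets.append(det(g.x_min + dx, g.y_min + dy, g.x_max + dx,
                                g.y_max + dy, g.class_id,
                                float(rng.uniform(0.3, 1.0))))
        for _ in range(rng.integers(0, 3)):  # spurious detections
            x0, y0 = rng.uniform(0, 60, 2)
            dets.append(det(x0, y0, x0 + 10, y0 + 10, int(rng.integers(3)),
                            float(rng.uniform(0.1, 0.9))))
        per_image.append((dets, gts))
    rep = evaluate_detections(per_image)
    assert rep.map == pytest.approx(hand_reference_evaluator(per_image), abs=1e-6)


def test_map_invariant_to_image_order():
    rng = np.random.default_rng(8)
    per_image = []
    for _ in range(5):
        x0, y0 = rng.uniform(0, 40, 2)
        g = gt(x0, y0, x0 + 12, y0 + 12, int(rng.integers(3)))
        d = det(g.x_min + 1, g.y_min, g.x_max + 1, g.y_max, g.class_id,
                float(rng.uniform(0.2, 1.0)))
        per_image.append(([d], [g]))
    rep1 = evaluate_detections(per_image)
    rep2 = evaluate_detections(per_image[::-1])
    assert rep1.map == pytest.approx(rep2.map, abs=1e-12)
    assert rep1.per_class_ap == rep2.per_class_ap


def test_interference_report_table_shape(tmp_path):
    from bbyolo.toy import make_toy_dataset, train_toy_detector  # light model
    from bbyolo.models import build_blueberry_yolo
    from bbyolo.anchors import cluster_anchors
    # an untrained tiny model suffices: the report harness is what is tested
    pairs = make_toy_dataset(6, seed0=50)
    boxes = np.array([[b.width, b.height] for _, a in pairs for b in a.boxes])
    pairs = pairs[:2]
    from bbyolo.toy import toy_detector_config
    anchors = cluster_anchors(boxes, k=12, seed=0, grids=(16, 8, 4, 2),
                              restarts=1)
    model = build_blueberry_yolo(toy_detector_config(anchors)).eval()
    datasets = {("fruit_density", "very_sparse"): pairs,
                ("fruit_density", "normal"): pairs}
    csv_path = tmp_path / "t.csv"
    table = interference_report(model, datasets, csv_path=csv_path,
                                json_path=tmp_path / "t.json")
    assert set(table) == {"light_intensity", "fruit_density", "shot_clarity"}
    assert all(len(v) == 3 for v in table.values())
    # identical detector on identical data -> identical mAP; missing -> None
    assert table["fruit_density"]["very_sparse"] == table["fruit_density"]["normal"]
    assert table["fruit_density"]["tightly_arranged"] is None
    assert table["light_intensity"]["normal"] is None
    assert csv_path.read_text().count("\n") == 10  # header + 9 rows
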
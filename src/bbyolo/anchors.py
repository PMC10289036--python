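"""Anchor priors by k-means++ clustering of box sizes under IoU distance.

Ground-truth (width, height) pairs are clustered with Lloyd iterations where
the distance between a box x and a centre c is A(x) = 1 - IoU(x, c), the IoU
being computed on boxes co-anchored at the origin (size-only).  Initial
centres follow k-means++: the first is uniform-random, each next centre is
drawn by roulette wheel with probability O(x) = A(x)^2 / sum A(x)^2 against
the nearest existing centre.  Centre updates are the arithmetic mean of the
member (w, h) pairs.

The packaged default prior set (``default_anchors``) covers four detection
scales (grids 152/76/38/19 at 608 input), three anchors per scale, one group
per ripeness class; a shared single set is what the detector head consumes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "AnchorSet", "iou_wh", "iou_wh_matrix", "selection_probabilities",
    "kmeanspp_init", "cluster_anchors", "default_anchors", "load_table2",
]

DEFAULT_GRIDS_4 = (152, 76, 38, 19)
DEFAULT_GRIDS_3 = (76, 38, 19)


@dataclass
class AnchorSet:
    """(width, height) priors grouped per detection scale.

    ``anchors`` has shape (n_levels, per_scale, 2) in input-image pixels;
    ``scale_grids`` gives the feature-map side length of each level at the
    native input size, largest grid (smallest stride) first.
    """

    anchors: np.ndarray
    scale_grids: tuple = DEFAULT_GRIDS_4

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.ndim != 3 or self.anchors.shape[2] != 2:
            raise ValueError("anchors must have shape (levels, per_scale, 2)")
        if self.anchors.shape[0] != len(self.scale_grids):
            raise ValueError("one anchor group per scale level required")
        if np.any(self.anchors <= 0):
            raise ValueError("anchor sizes must be positive")

    @property
    def n_levels(self) -> int:
        return self.anchors.shape[0]

    @property
    def per_scale(self) -> int:
        return self.anchors.shape[1]

    def flat(self) -> np.ndarray:
        return self.anchors.reshape(-1, 2)

    def normalized(self) -> "AnchorSet":
        """Sort anchors by area within each scale and scale groups by mean area.

        Smallest anchors go to the largest grid (finest stride).
        """
        a = self.anchors.copy()
        areas = a[..., 0] * a[..., 1]
        order_within = np.argsort(areas, axis=1)
        a = np.take_along_axis(a, order_within[..., None], axis=1)
        group_order = np.argsort((a[..., 0] * a[..., 1]).mean(axis=1))
        return AnchorSet(a[group_order], self.scale_grids)


def iou_wh(a, b) -> float:
    """Size-only IoU of two (w, h) boxes sharing a corner at the origin."""
    aw, ah = a
    bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("box sizes must be positive")
    inter = min(aw, bw) * min(ah, bh)
    return inter / (aw * ah + bw * bh - inter)


def iou_wh_matrix(boxes: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise size-only IoU between (n,2) boxes and (k,2) centres."""
    boxes = np.asarray(boxes, dtype=float)
    centers = np.asarray(centers, dtype=float)
    inter = (np.minimum(boxes[:, None, 0], centers[None, :, 0])
             * np.minimum(boxes[:, None, 1], centers[None, :, 1]))
    union = (boxes[:, 0] * boxes[:, 1])[:, None] + (centers[:, 0] * centers[:, 1])[None] - inter
    return inter / union


def selection_probabilities(distances: np.ndarray) -> np.ndarray:
    """k-means++ roulette probabilities O(x) = A(x)^2 / sum A(x)^2."""
    d2 = np.asarray(distances, dtype=float) ** 2
    total = d2.sum()
    if total <= 0:
        # all samples coincide with existing centres: fall back to uniform
        return np.full(d2.shape, 1.0 / d2.size)
    return d2 / total


def _min_distances(boxes, centers):
    return 1.0 - iou_wh_matrix(boxes, centers).max(axis=1)


def kmeanspp_init(boxes, k: int, seed=None, rng=None) -> np.ndarray:
    """k-means++ seeding under the IoU distance (roulette-wheel selection)."""
    boxes = np.asarray(boxes, dtype=float)
    if np.any(boxes <= 0):
        raise ValueError("box sizes must be positive")
    n_distinct = len(np.unique(boxes, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct boxes")
    rng = rng if rng is not None else np.random.default_rng(seed)
    centers = [boxes[rng.integers(len(boxes))]]
    while len(centers) < k:
        dists = _min_distances(boxes, np.asarray(centers))
        probs = selection_probabilities(dists)
        centers.append(boxes[rng.choice(len(boxes), p=probs)])
    return np.asarray(centers)


def _lloyd(boxes, k, rng, max_iter):
    centers = kmeanspp_init(boxes, k, rng=rng)
    assignment = None
    history = []
    for _ in range(max_iter):
        dist = 1.0 - iou_wh_matrix(boxes, centers)
        new_assignment = dist.argmin(axis=1)
        history.append(dist[np.arange(len(boxes)), new_assignment].sum())
        for c in range(k):
            members = boxes[new_assignment == c]
            if len(members):
                centers[c] = members.mean(axis=0)
            else:  # farthest-sample reseed
                far = dist[np.arange(len(boxes)), new_assignment].argmax()
                centers[c] = boxes[far]
                new_assignment[far] = c
        if assignment is not None and np.array_equal(assignment, new_assignment):
            break
        assignment = new_assignment
    final = (1.0 - iou_wh_matrix(boxes, centers).max(axis=1)).sum()
    return centers, assignment, np.asarray(history), final


def total_iou_distance(boxes, centers) -> float:
    """Sum over boxes of (1 - IoU to the nearest centre) — the clustering objective."""
    return float((1.0 - iou_wh_matrix(boxes, centers).max(axis=1)).sum())


def cluster_anchors(boxes, k: int = 12, seed: int = 0, n_levels: int = 4,
                    max_iter: int = 300, restarts: int = 10, grids=None,
                    return_state: bool = False):
    """k-means++ / Lloyd iterations under IoU distance -> normalised AnchorSet.

    Assignment sends each box to its nearest centre (largest size-only IoU);
    the centre update is the arithmetic mean of the member boxes.  An empty
    cluster is re-seeded from the sample farthest from its centre; iteration
    stops when the assignment stabilises.  The best of ``restarts``
    independent seedings (lowest total IoU distance) is returned — the
    mean-centre update is a heuristic for the IoU objective, so single runs
    can settle in local optima.
    """
    boxes = np.asarray(boxes, dtype=float)
    if len(boxes) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(boxes)}")
    if k % n_levels:
        raise ValueError("k must be divisible by the number of scale levels")
    best = None
    for r in range(max(restarts, 1)):
        rng = np.random.default_rng((seed, r))
        result = _lloyd(boxes, k, rng, max_iter)
        if best is None or result[3] < best[3]:
            best = result
    centers, assignment, history, final = best
    grids = tuple(grids) if grids is not None else (
        DEFAULT_GRIDS_4 if n_levels == 4 else DEFAULT_GRIDS_3)
    anchor_set = AnchorSet(
        centers.reshape(n_levels, k // n_levels, 2), grids).normalized()
    if return_state:
        return anchor_set, {"history": history, "assignment": assignment,
                            "total_distance": final}
    return anchor_set


def load_table2() -> dict:
    """Packaged default anchors: one 12-anchor group per ripeness class."""
    ref = importlib.resources.files("bbyolo.data").joinpath("table2.yaml")
    return yaml.safe_load(ref.read_text())


def default_anchors(class_group: str = "ripe") -> AnchorSet:
    """The packaged 4-scale anchor prior set for one ripeness class group.

    The detection head consumes a single shared set; the per-class groups
    are shipped as data for reporting and comparison.
    """
    cfg = load_table2()
    if class_group not in cfg["anchors"]:
        raise KeyError(f"unknown class group {class_group!r}; "
                       f"available: {sorted(cfg['anchors'])}")
    return AnchorSet(np.asarray(cfg["anchors"][class_group], dtype=float),
                     tuple(cfg["grids"]))


#: COCO-clustered priors of the three-scale reference baseline (strides 8/16/32).
YOLOV5_COCO_ANCHORS = AnchorSet(
    np.array([
        [[10, 13], [16, 30], [33, 23]],
        [[30, 61], [62, 45], [59, 119]],
        [[116, 90], [156, 198], [373, 326]],
    ], dtype=float),
    (80, 40, 20),  # grids at the baseline's native 640 input
)
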
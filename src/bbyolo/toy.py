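"""End-to-end toy recipe: small scenes, slim detector, CPU-minutes training.

This module fixes the problem sizes used for desk-scale verification of the
full pipeline (scene generation -> anchor clustering -> detector -> training
-> evaluation): 64-pixel scenes with 4-16 berries of 10-18 px, a detector at
1/8 of the full width with single-repeat blocks (~0.17 M parameters), and a
short SGD schedule with a raised learning rate suited to the tiny model and
dataset.  These sizes are the package's reference configuration for tests
and examples; the full-scale defaults live in the respective modules.
"""

from __future__ import annotations

import numpy as np

from .anchors import cluster_anchors
from .models import DetectorConfig, build_blueberry_yolo
from .scenes import SceneConfig, generate_scene
from .training import TrainConfig, train

__all__ = ["toy_scene_config", "make_toy_dataset", "toy_detector_config",
           "toy_train_config", "train_toy_detector"]

TOY_IMAGE_SIZE = 64


def toy_scene_config(seed: int = 0, density: str = "very_sparse",
                     clarity: str = "very_clear", light: str = "normal"
                     ) -> SceneConfig:
    """Scene parameters scaled to 64-px frames (berries 10-18 px across)."""
    return SceneConfig(
        image_size=TOY_IMAGE_SIZE, n_clusters=2, berries_per_cluster=(2, 4),
        berry_radius=(5, 9), occlusion_level=density, clarity_level=clarity,
        light_level=light, seed=seed)


def make_toy_dataset(n: int, seed0: int = 0, **strata):
    """n in-memory (image, annotation) pairs with consecutive seeds."""
    return [generate_scene(toy_scene_config(seed=seed0 + i, **strata))
            for i in range(n)]


def toy_detector_config(anchors, seed: int = 0) -> DetectorConfig:
    """Tiny four-scale variant: width 1/8, depth 1/3, 64-px input."""
    return DetectorConfig(input_size=TOY_IMAGE_SIZE, n_classes=3,
                          anchors=anchors, width_multiple=0.125,
                          depth_multiple=0.34, seed=seed)


def toy_train_config(seed: int = 0, loss: str = "eiou", epochs: int = 40
                     ) -> TrainConfig:
    """Short SGD schedule for the tiny variant.

    The raised learning rate (0.1 with cosine decay) and box weight 0.1
    compensate for the small batch count; the full-scale defaults
    (lr 0.001, weight decay 0.0005) stay in :class:`TrainConfig`.
    """
    return TrainConfig(initial_lr=0.1, weight_decay=0.0005, epochs=epochs,
                       batch_size=8, seed=seed, loss=loss,
                       box_weight=0.1, eval_conf_thresh=0.05)


def train_toy_detector(n_train: int = 200, n_val: int = 20, seed: int = 0,
                       loss: str = "eiou", epochs: int = 40, **strata):
    """Generate data, cluster anchors, build and train the tiny detector.

    Returns (model, best, history, val_pairs); anchors are clustered from
    the training boxes (k = 12 over 4 scales), as in the full pipeline.
    """
    train_pairs = make_toy_dataset(n_train, seed0=1000 + 100_000 * seed, **strata)
    val_pairs = make_toy_dataset(n_val, seed0=900_000 + 100_000 * seed, **strata)
    boxes = np.array([[b.width, b.height]
                      for _, ann in train_pairs for b in ann.boxes])
    anchors = cluster_anchors(boxes, k=12, seed=seed, grids=(16, 8, 4, 2))
    model = build_blueberry_yolo(toy_detector_config(anchors, seed=seed))
    best, history = train(model, train_pairs, val_pairs,
                          toy_train_config(seed=seed, loss=loss, epochs=epochs))
    return model, best, history, val_pairs
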
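"""Label-consistent data augmentation.

The operator menu is flips, scaling, panning (translation), rotation and
additive Gaussian noise, applied to the pixels and the annotation boxes by
the same transform.  Rotated boxes are re-tightened to the axis-aligned
hull of their transformed corners, clipped to the frame, and dropped when
the surviving area falls below a quarter of the transformed box's area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from .scenes import load_image, save_image
from .voc import (AnnotatedImage, BoundingBox, DatasetManifest, ManifestEntry,
                  read_voc_annotation, write_voc_annotation)

__all__ = ["AugmentSpec", "AllBoxesDroppedWarning", "apply_augmentation",
           "expand_dataset", "default_spec_sampler", "MIN_SURVIVING_AREA_FRACTION"]

GEOMETRIC_OPS = ("hflip", "vflip", "scale", "translate", "rotate")
NOISE_OPS = ("gaussian_noise",)

#: a clipped box survives only if >= this fraction of its transformed area remains
MIN_SURVIVING_AREA_FRACTION = 0.25


class AllBoxesDroppedWarning(UserWarning):
    """Raised as a warning when an augmentation removes every box."""


@dataclass
class AugmentSpec:
    """Ordered list of operations, e.g. ``[("hflip", {}), ("scale", {"factor": 0.5})]``."""

    ops: list
    seed: int = 0

    def __post_init__(self):
        for name, params in self.ops:
            if name not in GEOMETRIC_OPS + NOISE_OPS:
                raise ValueError(f"unknown op {name!r}")
            if name == "scale" and params.get("factor", 1.0) <= 0:
                raise ValueError("scale factor must be > 0")
            if name == "gaussian_noise" and params.get("sigma", 10.0) < 0:
                raise ValueError("noise sigma must be >= 0")


def _op_transform(name: str, params: dict, width: int, height: int) -> AffineTransform:
    """Forward affine map (x, y) -> (x', y') of one geometric op."""
    if name == "hflip":
        return AffineTransform(matrix=np.array(
            [[-1, 0, width], [0, 1, 0], [0, 0, 1]], dtype=float))
    if name == "vflip":
        return AffineTransform(matrix=np.array(
            [[1, 0, 0], [0, -1, height], [0, 0, 1]], dtype=float))
    if name == "scale":
        f = params["factor"]
        return AffineTransform(scale=(f, f))
    if name == "translate":
        return AffineTransform(translation=(params.get("dx", 0), params.get("dy", 0)))
    if name == "rotate":
        theta = np.deg2rad(params.get("degrees", 0.0))
        cx, cy = width / 2.0, height / 2.0
        shift = AffineTransform(translation=(-cx, -cy))
        rot = AffineTransform(rotation=theta)
        back = AffineTransform(translation=(cx, cy))
        return AffineTransform(matrix=back.params @ rot.params @ shift.params)
    raise ValueError(name)


def _transform_boxes(boxes, tform: AffineTransform, width: int, height: int):
    """Axis-aligned hulls of transformed corners, clipped; slivers dropped."""
    out = []
    for b in boxes:
        corners = np.array([[b.x_min, b.y_min], [b.x_max, b.y_min],
                            [b.x_max, b.y_max], [b.x_min, b.y_max]], dtype=float)
        tc = tform(corners)
        x0, y0 = tc.min(axis=0)
        x1, y1 = tc.max(axis=0)
        full_area = (x1 - x0) * (y1 - y0)
        cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
        cx1, cy1 = min(x1, float(width)), min(y1, float(height))
        if cx1 - cx0 <= 0 or cy1 - cy0 <= 0:
            continue
        if (cx1 - cx0) * (cy1 - cy0) < MIN_SURVIVING_AREA_FRACTION * full_area:
            continue
        out.append(BoundingBox(cx0, cy0, cx1, cy1, b.class_id, b.confidence))
    return out


def apply_augmentation(image: np.ndarray, ann: AnnotatedImage, spec: AugmentSpec):
    """Apply the spec's ops in order to pixels and boxes alike.

    Geometric ops keep the output frame at the input size (content moving
    out of frame is clipped); noise leaves geometry untouched.  Warns with
    :class:`AllBoxesDroppedWarning` if boxes existed and none survive.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.asarray(image, dtype=float)
    boxes = list(ann.boxes)
    h, w = img.shape[:2]
    for name, params in spec.ops:
        if name == "gaussian_noise":
            img = np.clip(img + rng.normal(0, params.get("sigma", 10.0), img.shape), 0, 255)
            continue
        tform = _op_transform(name, params, w, h)
        if name == "hflip":
            img = img[:, ::-1]
        elif name == "vflip":
            img = img[::-1]
        else:
            img = warp(img, tform.inverse, output_shape=(h, w),
                       order=1, preserve_range=True, mode="constant", cval=0.0)
        boxes = _transform_boxes(boxes, tform, w, h)
    if ann.boxes and not boxes:
        warnings.warn("augmentation removed every box", AllBoxesDroppedWarning)
    out_ann = AnnotatedImage(ann.image_id, ann.width, ann.height, boxes, ann.strata)
    return np.clip(img, 0, 255).astype(np.uint8), out_ann


def default_spec_sampler(rng: np.random.Generator) -> AugmentSpec:
    """Random combination from the augmentation menu (declared defaults)."""
    ops = []
    if rng.random() < 0.5:
        ops.append(("hflip", {}))
    if rng.random() < 0.2:
        ops.append(("vflip", {}))
    if rng.random() < 0.5:
        ops.append(("scale", {"factor": float(rng.uniform(0.8, 1.25))}))
    if rng.random() < 0.5:
        ops.append(("translate", {"dx": float(rng.uniform(-30, 30)),
                                  "dy": float(rng.uniform(-30, 30))}))
    if rng.random() < 0.5:
        ops.append(("rotate", {"degrees": float(rng.uniform(-15, 15))}))
    if rng.random() < 0.5:
        ops.append(("gaussian_noise", {"sigma": float(rng.uniform(3, 12))}))
    if not ops:
        ops.append(("hflip", {}))
    return AugmentSpec(ops, seed=int(rng.integers(2 ** 31)))


def expand_dataset(manifest: DatasetManifest, factor: float, out_dir,
                   spec_sampler=default_spec_sampler, seed: int = 0
                   ) -> DatasetManifest:
    """Grow a dataset to ``round(factor * n)`` items, originals retained.

    Augmented copies cycle through the source images; each gets a spec drawn
    from ``spec_sampler`` and is written next to a transformed annotation.
    """
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_total = round(factor * len(manifest))
    entries = list(manifest.entries)
    n_new = n_total - len(entries)
    for i in range(n_new):
        src = manifest.entries[i % len(manifest.entries)]
        img = load_image(src.image_path)
        ann = read_voc_annotation(src.annotation_path)
        spec = spec_sampler(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AllBoxesDroppedWarning)
            aug_img, aug_ann = apply_augmentation(img, ann, spec)
        image_id = f"{ann.image_id}_aug{i:05d}"
        aug_ann = replace(aug_ann, image_id=image_id)
        img_path = out_dir / "images" / f"{image_id}.png"
        ann_path = out_dir / "annotations" / f"{image_id}.xml"
        save_image(aug_img, img_path)
        write_voc_annotation(aug_ann, ann_path)
        entries.append(ManifestEntry(str(img_path), str(ann_path), ann.strata))
    out = DatasetManifest(entries, manifest.split)
    out.save(out_dir / "manifest.jsonl")
    return out
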
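"""Synthetic berry-cluster scenes with exact ground truth.

Scenes emulate the three ripeness appearances — ripe berries are dark
purple and dim, semi-ripe red/lavender and bright, unripe green and very
bright — and the three interference factors (light intensity, fruit
density, shot clarity), each with the closed three-level vocabulary used
for dataset stratification.  Berries are shaded ellipses with a radial
gradient and a specular highlight on a foliage-like background: the point
is controllable difficulty and pixel-exact labels, not realism.

Ground-truth boxes are amodal (full berry extent, occluded or not).
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .voc import (AnnotatedImage, BoundingBox, DatasetManifest, ManifestEntry,
                  STRATA_VOCAB, write_voc_annotation)

__all__ = [
    "SceneConfig", "BERRY_COLORS", "OCCLUSION_IOU_CAPS",
    "generate_scene", "generate_dataset", "degrade", "save_image", "load_image",
]

#: class-conditional base colour (RGB) and brightness scale
BERRY_COLORS = {
    0: ((74, 48, 112), 0.80),    # ripe: dark purple, low brightness
    1: ((196, 104, 166), 1.05),  # semi-ripe: red/lavender, bright
    2: ((148, 204, 96), 1.20),   # unripe: green, very bright
}

#: maximum allowed pairwise box IoU per fruit-density stratum
OCCLUSION_IOU_CAPS = {
    "very_sparse": 0.0,
    "normal": 0.30,
    "tightly_arranged": 0.70,
}

_BLUR_SIGMA = {"very_clear": 0.0, "partially_blurred": 0.45, "very_blurry": 0.9}


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene."""

    image_size: int = 608
    n_clusters: int = 4
    berries_per_cluster: tuple = (3, 7)
    berry_radius: tuple = (12, 26)
    class_mixture: tuple = (1 / 3, 1 / 3, 1 / 3)
    occlusion_level: str = "normal"
    light_level: str = "normal"
    clarity_level: str = "very_clear"
    background_style: str = "foliage"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if self.berries_per_cluster[0] > self.berries_per_cluster[1] or \
                self.berry_radius[0] > self.berry_radius[1]:
            raise ValueError("empty range")
        if self.occlusion_level not in STRATA_VOCAB["fruit_density"]:
            raise ValueError(f"bad occlusion_level {self.occlusion_level!r}")
        if self.light_level not in STRATA_VOCAB["light_intensity"]:
            raise ValueError(f"bad light_level {self.light_level!r}")
        if self.clarity_level not in STRATA_VOCAB["shot_clarity"]:
            raise ValueError(f"bad clarity_level {self.clarity_level!r}")
        if self.background_style not in ("foliage", "plain"):
            raise ValueError(f"bad background_style {self.background_style!r}")

    @property
    def strata(self) -> dict:
        return {"light_intensity": self.light_level,
                "fruit_density": self.occlusion_level,
                "shot_clarity": self.clarity_level}


def _background(size: int, style: str, rng) -> np.ndarray:
    if style == "plain":
        img = np.full((size, size, 3), (118, 122, 110), dtype=float)
        img += rng.normal(0, 3, img.shape)
        return img
    # foliage: low-frequency green mottling
    coarse = rng.uniform(0.5, 1.4, (max(size // 32, 2), max(size // 32, 2)))
    mod = ndimage.zoom(coarse, size / coarse.shape[0], order=1)[:size, :size]
    mod = ndimage.gaussian_filter(mod, sigma=size / 64)
    base = np.array([44, 78, 38], dtype=float)
    img = base[None, None, :] * mod[..., None]
    img += rng.normal(0, 4, img.shape)
    return img


def _box_iou_xyxy(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua


def _render_berry(img, cx, cy, rx, ry, color, brightness, rng):
    """Shaded ellipse with radial gradient and specular highlight."""
    size = img.shape[0]
    x0, x1 = max(int(cx - rx), 0), min(int(np.ceil(cx + rx)) + 1, size)
    y0, y1 = max(int(cy - ry), 0), min(int(np.ceil(cy + ry)) + 1, size)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    r2 = ((xs + 0.5 - cx) / rx) ** 2 + ((ys + 0.5 - cy) / ry) ** 2
    inside = r2 <= 1.0
    if not inside.any():
        return
    shade = brightness * (0.45 + 0.55 * (1.0 - r2[inside]) ** 0.8)
    col = np.asarray(color, dtype=float) * (1.0 + rng.normal(0, 0.04, 3))
    patch = shade[:, None] * col[None, :]
    # specular highlight, upper-left quadrant
    hx, hy = cx - 0.35 * rx, cy - 0.35 * ry
    h2 = ((xs + 0.5 - hx) / (0.28 * rx)) ** 2 + ((ys + 0.5 - hy) / (0.28 * ry)) ** 2
    glint = np.exp(-h2[inside])
    patch += 130.0 * glint[:, None]
    img[y0:y1, x0:x1][inside] = patch


def generate_scene(cfg: SceneConfig, return_log: bool = False):
    """Render one scene; returns ``(image_uint8, AnnotatedImage)``.

    With ``return_log`` a placement log (list of dicts with box, class,
    centre and radii) is appended to the return tuple.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    img = _background(size, cfg.background_style, rng)
    cap = OCCLUSION_IOU_CAPS[cfg.occlusion_level]
    margin = cfg.berry_radius[1] + 2

    placements = []  # dicts with box/class/center/radii
    for _ in range(cfg.n_clusters):
        ccx = rng.uniform(margin, size - margin)
        ccy = rng.uniform(margin, size - margin)
        n_berries = int(rng.integers(cfg.berries_per_cluster[0],
                                     cfg.berries_per_cluster[1] + 1))
        spread = cfg.berry_radius[1] * (2.8 if cap == 0.0 else 2.0 if cap <= 0.3 else 1.2)
        for _ in range(n_berries):
            placed = False
            for _attempt in range(60):
                rx = rng.uniform(*cfg.berry_radius)
                ry = rx * rng.uniform(0.85, 1.15)
                bx = ccx + rng.normal(0, spread)
                by = ccy + rng.normal(0, spread)
                box = (bx - rx, by - ry, bx + rx, by + ry)
                if box[0] < 0 or box[1] < 0 or box[2] > size or box[3] > size:
                    continue  # would cross the frame: resample
                if any(_box_iou_xyxy(box, p["box"]) > cap + 1e-12
                       for p in placements):
                    continue
                placements.append({"box": box, "center": (bx, by),
                                   "radii": (rx, ry),
                                   "class_id": int(rng.choice(3, p=cfg.class_mixture))})
                placed = True
                break
            if not placed:
                pass  # dropped: never emitted without a box

    # draw back-to-front by y so lower berries occlude upper ones
    for p in sorted(placements, key=lambda p: p["center"][1]):
        color, brightness = BERRY_COLORS[p["class_id"]]
        _render_berry(img, *p["center"], *p["radii"], color, brightness, rng)

    img = np.clip(img, 0, 255)
    if cfg.light_level == "backlighting":
        img = degrade(img, "backlight", 0.7)
    elif cfg.light_level == "strong":
        img = degrade(img, "strong_light", 0.7)
    sigma_level = _BLUR_SIGMA[cfg.clarity_level]
    if sigma_level:
        img = degrade(img, "blur", sigma_level)
    img = np.clip(img, 0, 255).astype(np.uint8)

    boxes = [BoundingBox(*p["box"], class_id=p["class_id"]) for p in placements]
    ann = AnnotatedImage(f"scene_{cfg.seed}", size, size, boxes, cfg.strata)
    if return_log:
        return img, ann, placements
    return img, ann


def degrade(image, kind: str, level: float):
    """Annotation-preserving image degradation; ``level`` 0 is the identity.

    blur: Gaussian, sigma grows linearly with level (monotone sharpness loss);
    backlight: luminance scaled down; strong_light: brightness/washout up.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    img = np.asarray(image, dtype=float)
    if level == 0.0:
        out = img
    elif kind == "blur":
        out = ndimage.gaussian_filter(img, sigma=(3.0 * level, 3.0 * level, 0))
    elif kind == "backlight":
        out = img * (1.0 - 0.55 * level)
    elif kind == "strong_light":
        out = img * (1.0 + 0.25 * level) + 70.0 * level
    else:
        raise ValueError(f"unknown degradation kind {kind!r}")
    out = np.clip(out, 0, 255)
    if isinstance(image, np.ndarray) and image.dtype == np.uint8:
        return out.astype(np.uint8)
    return out


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def generate_dataset(cfg_grid, n_per_cfg: int, out_dir, base_seed: int = 0
                     ) -> DatasetManifest:
    """Write ``n_per_cfg`` scenes per config (PNG + VOC XML + manifest)."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    entries = []
    for ci, cfg in enumerate(cfg_grid):
        for i in range(n_per_cfg):
            seed = (base_seed * 1_000_003 + cfg.seed * 1_009 + ci * 131 + i) % (2 ** 31)
            scfg = replace(cfg, seed=seed)
            image_id = f"scene_{ci:03d}_{i:05d}"
            img_path = out_dir / "images" / f"{image_id}.png"
            ann_path = out_dir / "annotations" / f"{image_id}.xml"
            if img_path.exists():
                raise FileExistsError(f"id collision: {img_path}")
            img, ann = generate_scene(scfg)
            ann = AnnotatedImage(image_id, ann.width, ann.height, ann.boxes, ann.strata)
            save_image(img, img_path)
            write_voc_annotation(ann, ann_path)
            entries.append(ManifestEntry(str(img_path), str(ann_path), ann.strata))
    manifest = DatasetManifest(entries)
    manifest.save(out_dir / "manifest.jsonl")
    return manifest
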
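"""Annotation data model and Pascal VOC / YOLO label I/O.

Boxes are stored internally as continuous ``[x_min, x_max) x [y_min, y_max)``
pixel intervals with the origin at the top-left.  On disk, VOC XML uses
1-based inclusive integer corners; the conversion happens on read/write so
that integer boxes round-trip exactly.

Interference strata (light intensity, fruit density, shot clarity) ride
along in a custom ``<strata>`` element that other VOC consumers ignore.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_NAMES", "STRATA_VOCAB", "BoundingBox", "Detection", "AnnotatedImage",
    "ManifestEntry", "DatasetManifest", "class_name_to_id",
    "read_voc_annotation", "write_voc_annotation",
    "to_yolo_labels", "from_yolo_labels", "split_dataset",
]

CLASS_NAMES = ("ripe", "semi-ripe", "unripe")

#: closed vocabularies of the three interference factors
STRATA_VOCAB = {
    "light_intensity": ("backlighting", "normal", "strong"),
    "fruit_density": ("very_sparse", "normal", "tightly_arranged"),
    "shot_clarity": ("very_blurry", "partially_blurred", "very_clear"),
}


def class_name_to_id(name: str, aliases: dict | None = None) -> int:
    """Map a label string to {0: ripe, 1: semi-ripe, 2: unripe}.

    Case-insensitive; ``aliases`` maps extra accepted spellings to canonical
    names (e.g. ``{"mature": "ripe"}``).
    """
    key = name.strip().lower()
    if aliases:
        key = {k.lower(): v for k, v in aliases.items()}.get(key, key)
    try:
        return CLASS_NAMES.index(key)
    except ValueError:
        raise ValueError(
            f"unknown class name {name!r}; accepted: {list(CLASS_NAMES)}"
            + (f" plus aliases {sorted(aliases)}" if aliases else "")) from None


@dataclass
class BoundingBox:
    """Axis-aligned box; ``confidence`` is None for ground truth."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int
    confidence: float | None = None

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")
        if self.class_id not in (0, 1, 2):
            raise ValueError(f"class_id must be 0, 1 or 2, got {self.class_id}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_xyxy(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)

    def clipped(self, width: float, height: float) -> "BoundingBox":
        return replace(self,
                       x_min=max(0.0, min(self.x_min, width)),
                       y_min=max(0.0, min(self.y_min, height)),
                       x_max=max(0.0, min(self.x_max, width)),
                       y_max=max(0.0, min(self.y_max, height)))


#: a detection is a box that carries a confidence score
Detection = BoundingBox


@dataclass
class AnnotatedImage:
    """An image's identity, size, labelled boxes and optional strata tags."""

    image_id: str
    width: int
    height: int
    boxes: list = field(default_factory=list)
    strata: dict | None = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > self.width or b.y_max > self.height:
                raise ValueError(f"box {b} exceeds image bounds "
                                 f"({self.width}x{self.height})")
        if self.strata is not None:
            for key, value in self.strata.items():
                if key not in STRATA_VOCAB:
                    raise ValueError(f"unknown stratum {key!r}")
                if value not in STRATA_VOCAB[key]:
                    raise ValueError(
                        f"{key}={value!r} not in {STRATA_VOCAB[key]}")


@dataclass
class ManifestEntry:
    image_path: str
    annotation_path: str
    strata: dict | None = None


@dataclass
class DatasetManifest:
    """Newline-delimited-JSON list of (image, annotation, strata) entries."""

    entries: list = field(default_factory=list)
    split: str = "unsplit"

    def __post_init__(self):
        if self.split not in ("train", "val", "test", "unsplit"):
            raise ValueError(f"bad split name {self.split!r}")
        paths = [e.image_path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image paths in manifest")

    def __len__(self):
        return len(self.entries)

    def save(self, path):
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps({
                    "image": e.image_path, "annotation": e.annotation_path,
                    "strata": e.strata, "split": self.split}) + "\n")

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        entries, split = [], "unsplit"
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                split = rec.get("split", "unsplit")
                entries.append(ManifestEntry(rec["image"], rec["annotation"],
                                             rec.get("strata")))
        return cls(entries, split)


# -- Pascal VOC XML ----------------------------------------------------------

def read_voc_annotation(xml_path, aliases: dict | None = None) -> AnnotatedImage:
    """Parse one VOC XML file into the continuous-coordinate data model."""
    xml_path = Path(xml_path)
    try:
        tree = ET.parse(xml_path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML in {xml_path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    image_id = root.findtext("filename", default=xml_path.stem)
    image_id = Path(image_id).stem
    boxes = []
    for obj in root.iter("object"):
        cls = class_name_to_id(obj.findtext("name"), aliases)
        bb = obj.find("bndbox")
        # disk: 1-based inclusive integers -> internal: 0-based half-open
        x_min = float(bb.findtext("xmin")) - 1.0
        y_min = float(bb.findtext("ymin")) - 1.0
        x_max = float(bb.findtext("xmax"))
        y_max = float(bb.findtext("ymax"))
        boxes.append(BoundingBox(x_min, y_min, x_max, y_max, cls))
    strata = None
    snode = root.find("strata")
    if snode is not None:
        strata = {child.tag: child.text for child in snode}
    return AnnotatedImage(image_id, width, height, boxes, strata)


def write_voc_annotation(ann: AnnotatedImage, xml_path) -> None:
    """Emit VOC-dialect XML (integer 1-based inclusive corners)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    if ann.strata:
        snode = ET.SubElement(root, "strata")
        for key, value in ann.strata.items():
            ET.SubElement(snode, key).text = value
    for b in ann.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = CLASS_NAMES[b.class_id]
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(b.x_min)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(b.y_min)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(b.x_max)))
        ET.SubElement(bb, "ymax").text = str(int(round(b.y_max)))
    ET.indent(root)
    ET.ElementTree(root).write(xml_path, encoding="unicode")


# -- YOLO txt labels ---------------------------------------------------------

def to_yolo_labels(ann: AnnotatedImage) -> list:
    """Normalised (class_id, cx, cy, w, h) tuples in [0, 1]."""
    if ann.width <= 0 or ann.height <= 0:
        raise ValueError("zero-size image")
    out = []
    for b in ann.boxes:
        out.append((b.class_id,
                    (b.x_min + b.x_max) / (2.0 * ann.width),
                    (b.y_min + b.y_max) / (2.0 * ann.height),
                    b.width / ann.width,
                    b.height / ann.height))
    return out


def from_yolo_labels(labels, width: int, height: int,
                     image_id: str = "img") -> AnnotatedImage:
    boxes = []
    for cls, cx, cy, w, h in labels:
        boxes.append(BoundingBox(
            (cx - w / 2.0) * width, (cy - h / 2.0) * height,
            (cx + w / 2.0) * width, (cy + h / 2.0) * height, int(cls)))
    return AnnotatedImage(image_id, width, height, boxes)


# -- dataset splitting --------------------------------------------------------

def split_dataset(manifest: DatasetManifest, fractions=(0.7, 0.1, 0.2),
                  seed: int = 0, stratify_by: str | None = None):
    """Deterministic random train/val/test partition.

    Train and validation sizes are floor(f_i * n); the test split absorbs
    the remainder (floor-then-remainder, which reproduces the reference
    counts 18,498 / 2,642 / 5,286 for n = 26,426 at 70/10/20).  With
    ``stratify_by`` set to a stratum key, the same rule is applied within
    each stratum value.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)

    def partition(entries):
        idx = rng.permutation(len(entries))
        n_train = int(fractions[0] * len(entries))
        n_val = int(fractions[1] * len(entries))
        train = [entries[i] for i in idx[:n_train]]
        val = [entries[i] for i in idx[n_train:n_train + n_val]]
        test = [entries[i] for i in idx[n_train + n_val:]]
        return train, val, test

    if stratify_by is None:
        groups = [manifest.entries]
    else:
        by_value = {}
        for e in manifest.entries:
            key = (e.strata or {}).get(stratify_by)
            by_value.setdefault(key, []).append(e)
        groups = [by_value[k] for k in sorted(by_value, key=str)]

    train, val, test = [], [], []
    for g in groups:
        a, b, c = partition(g)
        train += a
        val += b
        test += c
    return (DatasetManifest(train, "train"),
            DatasetManifest(val, "val"),
            DatasetManifest(test, "test"))
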
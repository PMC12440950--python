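"""Annotation data model, readers/writers, dataset split and statistics.

Two on-disk dialects are supported losslessly:

* COCO-JSON (``images`` / ``annotations`` / ``categories``) with
  polygon segmentations and xywh boxes;
* per-image normalized-polygon text (one ``class x1 y1 x2 y2 …`` line
  per instance, coordinates relative to the image size), alongside a
  class-list file.

Instance size bins follow the usual small-object convention at a
1920×1088 reference resolution: Tiny ≤ 16², Small ≤ 32², Medium ≤ 128²,
Large > 128² (bounding-box area, inclusive upper bounds except Large).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

DEFAULT_CLASSES = ("soybean", "poaceous_weed", "broadleaf_weed")
REFERENCE_RESOLUTION = (1920, 1088)  # (width, height)


class ParseError(ValueError):
    """Malformed annotation file; message names the offending record."""


class SizeBin(str, Enum):
    TINY = "Tiny"
    SMALL = "Small"
    MEDIUM = "Medium"
    LARGE = "Large"


_BIN_EDGES = (16 ** 2, 32 ** 2, 128 ** 2)


@dataclass
class ImageRecord:
    image_id: int
    width: int
    height: int
    file_name: Optional[str] = None
    pixels: Optional[np.ndarray] = None  # (H, W, 3) uint8

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image {self.image_id}: non-positive size")


@dataclass
class InstanceAnnotation:
    image_id: int
    class_label: str
    polygon: np.ndarray  # (n, 2) float pixel coordinates (x, y)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64).reshape(-1, 2)
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.polygon_area <= 0:
            raise ValueError("polygon area must be positive")

    @property
    def bbox(self) -> Tuple[float, float, float, float]:
        x1, y1 = self.polygon.min(axis=0)
        x2, y2 = self.polygon.max(axis=0)
        return float(x1), float(y1), float(x2), float(y2)

    @property
    def bbox_area(self) -> float:
        x1, y1, x2, y2 = self.bbox
        return (x2 - x1) * (y2 - y1)

    @property
    def polygon_area(self) -> float:
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class AnnotationSet:
    images: List[ImageRecord] = field(default_factory=list)
    instances: List[InstanceAnnotation] = field(default_factory=list)
    classes: Tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = {im.image_id for im in self.images}
        if len(ids) != len(self.images):
            raise ValueError("duplicate image ids")
        for inst in self.instances:
            if inst.image_id not in ids:
                raise ValueError(f"instance references unknown image {inst.image_id}")
            if inst.class_label not in self.classes:
                raise ValueError(f"unknown class label {inst.class_label!r}")

    def image(self, image_id: int) -> ImageRecord:
        for im in self.images:
            if im.image_id == image_id:
                return im
        raise KeyError(image_id)

    def instances_of(self, image_id: int) -> List[InstanceAnnotation]:
        return [i for i in self.instances if i.image_id == image_id]

    def class_index(self, label: str) -> int:
        return self.classes.index(label)

    def subset(self, image_ids: Sequence[int]) -> "AnnotationSet":
        keep = set(image_ids)
        return AnnotationSet(
            images=[im for im in self.images if im.image_id in keep],
            instances=[i for i in self.instances if i.image_id in keep],
            classes=self.classes,
        )


# ---------------------------------------------------------------------------
# size bins
# ---------------------------------------------------------------------------

def size_bin(
    instance: InstanceAnnotation,
    image_size: Optional[Tuple[int, int]] = None,
    reference_resolution: Tuple[int, int] = REFERENCE_RESOLUTION,
) -> SizeBin:
    """Bin an instance by bounding-box area at the reference resolution.

    ``image_size`` is the (width, height) the polygon coordinates live
    in; omit it when they are already at the reference resolution.
    """
    area = instance.bbox_area
    if area <= 0:
        raise ValueError("instance bounding-box area must be positive")
    if image_size is not None:
        w, h = image_size
        rw, rh = reference_resolution
        area *= (rw / w) * (rh / h)
    if area <= _BIN_EDGES[0]:
        return SizeBin.TINY
    if area <= _BIN_EDGES[1]:
        return SizeBin.SMALL
    if area <= _BIN_EDGES[2]:
        return SizeBin.MEDIUM
    return SizeBin.LARGE


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_dataset(
    a: AnnotationSet,
    ratios: Tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> Tuple[AnnotationSet, AnnotationSet, AnnotationSet]:
    """Image-level train/val/test split with largest-remainder rounding."""
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(a.images)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} images into {len(ratios)} subsets")
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    order = np.argsort([-(e - s) for e, s in zip(exact, sizes)], kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    sizes = [max(s, 1) for s in sizes]
    while sum(sizes) > n:
        sizes[int(np.argmax(sizes))] -= 1
    rng = np.random.default_rng(seed)
    ids = [im.image_id for im in a.images]
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    out = []
    start = 0
    for s in sizes:
        out.append(a.subset(shuffled[start : start + s]))
        start += s
    return tuple(out)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def dataset_statistics(a: AnnotationSet) -> Dict:
    """Per-class and per-size-bin instance counts with proportions."""
    per_class = {c: 0 for c in a.classes}
    per_bin = {b.value: 0 for b in SizeBin}
    sizes = {im.image_id: (im.width, im.height) for im in a.images}
    for inst in a.instances:
        per_class[inst.class_label] += 1
        per_bin[size_bin(inst, sizes[inst.image_id]).value] += 1
    total = len(a.instances)
    denom = max(total, 1)
    return {
        "total_instances": total,
        "n_images": len(a.images),
        "per_class": per_class,
        "per_bin": per_bin,
        "class_proportions": {c: v / denom for c, v in per_class.items()},
        "bin_proportions": {b: v / denom for b, v in per_bin.items()},
    }


# ---------------------------------------------------------------------------
# COCO-JSON dialect
# ---------------------------------------------------------------------------

def write_coco(a: AnnotationSet, path) -> None:
    doc = {
        "images": [
            {
                "id": im.image_id,
                "width": im.width,
                "height": im.height,
                **({"file_name": im.file_name} if im.file_name else {}),
            }
            for im in a.images
        ],
        "categories": [
            {"id": i + 1, "name": c} for i, c in enumerate(a.classes)
        ],
        "annotations": [],
    }
    for k, inst in enumerate(a.instances):
        x1, y1, x2, y2 = inst.bbox
        doc["annotations"].append(
            {
                "id": k + 1,
                "image_id": inst.image_id,
                "category_id": a.class_index(inst.class_label) + 1,
                "segmentation": [inst.polygon.reshape(-1).tolist()],
                "bbox": [x1, y1, x2 - x1, y2 - y1],
                "area": inst.polygon_area,
                "iscrowd": 0,
            }
        )
    Path(path).write_text(json.dumps(doc))


def read_coco(path) -> AnnotationSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: not valid JSON ({e})") from e
    try:
        cats = sorted(doc["categories"], key=lambda c: c["id"])
        classes = tuple(c["name"] for c in cats)
        cat_to_label = {c["id"]: c["name"] for c in cats}
        images = [
            ImageRecord(
                image_id=im["id"],
                width=im["width"],
                height=im["height"],
                file_name=im.get("file_name"),
            )
            for im in doc["images"]
        ]
    except (KeyError, TypeError) as e:
        raise ParseError(f"{path}: malformed images/categories section ({e})") from e
    instances = []
    for ann in doc.get("annotations", []):
        try:
            seg = ann["segmentation"][0]
            instances.append(
                InstanceAnnotation(
                    image_id=ann["image_id"],
                    class_label=cat_to_label[ann["category_id"]],
                    polygon=np.asarray(seg, float).reshape(-1, 2),
                )
            )
        except (KeyError, IndexError, TypeError, ValueError) as e:
            raise ParseError(
                f"{path}: malformed annotation id={ann.get('id')!r} ({e})"
            ) from e
    return AnnotationSet(images=images, instances=instances, classes=classes)


# ---------------------------------------------------------------------------
# normalized-polygon text dialect
# ---------------------------------------------------------------------------

def write_yolo_polygons(a: AnnotationSet, directory) -> None:
    """Write `labels/<image>.txt` + `classes.txt` + `image_sizes.json`."""
    directory = Path(directory)
    (directory / "labels").mkdir(parents=True, exist_ok=True)
    (directory / "classes.txt").write_text("\n".join(a.classes) + "\n")
    sizes = {}
    for im in a.images:
        stem = im.file_name.rsplit(".", 1)[0] if im.file_name else f"{im.image_id:06d}"
        sizes[stem] = [im.image_id, im.width, im.height]
        lines = []
        for inst in a.instances_of(im.image_id):
            norm = inst.polygon / np.array([im.width, im.height], float)
            coords = " ".join(f"{v:.8f}" for v in norm.reshape(-1))
            lines.append(f"{a.class_index(inst.class_label)} {coords}")
        (directory / "labels" / f"{stem}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    (directory / "image_sizes.json").write_text(json.dumps(sizes))


def read_yolo_polygons(directory) -> AnnotationSet:
    directory = Path(directory)
    classes_file = directory / "classes.txt"
    if not classes_file.exists():
        raise ParseError(f"{directory}: missing classes.txt")
    classes = tuple(l for l in classes_file.read_text().splitlines() if l.strip())
    sizes_file = directory / "image_sizes.json"
    if sizes_file.exists():
        sizes = json.loads(sizes_file.read_text())
    else:
        sizes = _sizes_from_images(directory)
    images, instances = [], []
    for stem, (image_id, w, h) in sorted(sizes.items()):
        images.append(ImageRecord(image_id=image_id, width=w, height=h, file_name=f"{stem}.png"))
        label_file = directory / "labels" / f"{stem}.txt"
        if not label_file.exists():
            continue
        for ln, line in enumerate(label_file.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                cls = int(parts[0])
                coords = np.asarray([float(v) for v in parts[1:]], float)
                if coords.size < 6 or coords.size % 2:
                    raise ValueError("need >=3 (x, y) pairs")
                poly = coords.reshape(-1, 2) * np.array([w, h], float)
                instances.append(
                    InstanceAnnotation(image_id=image_id, class_label=classes[cls], polygon=poly)
                )
            except (ValueError, IndexError) as e:
                raise ParseError(f"{label_file}:{ln}: malformed record ({e})") from e
    return AnnotationSet(images=images, instances=instances, classes=classes)


def _sizes_from_images(directory: Path) -> Dict[str, List[int]]:
    from PIL import Image

    sizes = {}
    img_dir = directory / "images"
    files = sorted(img_dir.glob("*.png")) if img_dir.exists() else []
    if not files:
        raise ParseError(f"{directory}: no image_sizes.json and no images/*.png")
    for i, f in enumerate(files):
        with Image.open(f) as im:
            w, h = im.size
        sizes[f.stem] = [i, w, h]
    return sizes


def load_image_pixels(a: AnnotationSet, directory) -> None:
    """Populate ``pixels`` for every image from `<directory>/images/*.png`."""
    from PIL import Image

    directory = Path(directory)
    for im in a.images:
        name = im.file_name or f"{im.image_id:06d}.png"
        with Image.open(directory / "images" / name) as fh:
            im.pixels = np.asarray(fh.convert("RGB"))
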
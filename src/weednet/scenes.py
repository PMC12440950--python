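"""Procedural crop/weed field-scene generator.

Emulates the statistical structure of close-range field imagery so the
whole pipeline is testable without any real data: three plant shape
families (broad round crop leaves, thin elongated grass blades, lobed
broadleaf-weed rosettes), class-conditional green palettes whose
overlap is controlled by a separability knob, back-to-front placement
with a tunable occlusion rate, diffuse or harsh illumination with
optional specular spots, and a target size-bin mixture expressed at the
1920×1088 reference resolution.

Annotations record the *visible* polygon of each instance: parts hidden
by later (closer) plants are removed, and fully hidden instances are
dropped, matching how canopy occlusion behaves in real annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import shapely.geometry as sg
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon

from .annotations import (
    AnnotationSet,
    DEFAULT_CLASSES,
    ImageRecord,
    InstanceAnnotation,
    REFERENCE_RESOLUTION,
    SizeBin,
)

# class mixture of the three-way field scenario (crop-dominant weeds):
# soybean : poaceous : broadleaf at the proportions of a typical
# infested soybean plot (weeds dominate instance counts)
DEFAULT_CLASS_MIX = (0.136, 0.761, 0.103)
# size mixture (Tiny, Small, Medium, Large) of close-range field scenes
DEFAULT_SIZE_QUOTA = (0.1853, 0.2507, 0.3566, 0.2073)

_BIN_RANGES = {  # bbox-area ranges at the reference resolution
    SizeBin.TINY: (6.0 ** 2, 16.0 ** 2),
    SizeBin.SMALL: (16.0 ** 2, 32.0 ** 2),
    SizeBin.MEDIUM: (32.0 ** 2, 128.0 ** 2),
    SizeBin.LARGE: (128.0 ** 2, 256.0 ** 2),
}
_BINS = (SizeBin.TINY, SizeBin.SMALL, SizeBin.MEDIUM, SizeBin.LARGE)

MIN_VISIBLE_AREA = 1.0  # px² below which an occluded instance is dropped


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    seed: int = 0
    image_size: Tuple[int, int] = (640, 640)  # (height, width)
    n_instances: int = 30
    classes: Tuple[str, ...] = DEFAULT_CLASSES
    class_mix: Tuple[float, ...] = DEFAULT_CLASS_MIX
    size_quota: Tuple[float, float, float, float] = DEFAULT_SIZE_QUOTA
    occlusion_rate: float = 0.3
    lighting: str = "diffuse"  # or "harsh"
    specular_prob: float = 0.5
    separability: float = 0.7  # 0 = identical palettes, 1 = well separated
    size_scale: float = 1.0    # capture-distance zoom: >1 means closer range,
                               # enlarging every instance relative to the frame

    def __post_init__(self):
        if isinstance(self.image_size, int):
            self.image_size = (self.image_size, self.image_size)
        if self.n_instances < 0:
            raise ValueError("n_instances must be >= 0")
        if abs(sum(self.class_mix) - 1) > 1e-3:
            raise ValueError("class_mix must sum to 1")
        if abs(sum(self.size_quota) - 1) > 1e-3:
            raise ValueError("size_quota must sum to 1")
        self.class_mix = tuple(np.asarray(self.class_mix) / sum(self.class_mix))
        self.size_quota = tuple(np.asarray(self.size_quota) / sum(self.size_quota))
        if not 0.0 <= self.occlusion_rate <= 1.0:
            raise ValueError("occlusion_rate must lie in [0, 1]")
        if self.size_scale <= 0:
            raise ValueError("size_scale must be positive")
        if self.lighting not in ("diffuse", "harsh"):
            raise ValueError("lighting must be 'diffuse' or 'harsh'")
        h, w = self.image_size
        ref_area = REFERENCE_RESOLUTION[0] * REFERENCE_RESOLUTION[1]
        for b, q in zip(_BINS, self.size_quota):
            _, hi = _BIN_RANGES[b]
            if q > 0 and hi * (h * w) / ref_area < 1.0:
                raise ValueError(
                    f"size quota infeasible: bin {b.value} needs sub-pixel "
                    f"instances at image size {h}x{w}"
                )


# ---------------------------------------------------------------------------
# shape families
# ---------------------------------------------------------------------------

def _crop_leaf_cluster(rng: np.random.Generator) -> np.ndarray:
    """Rosette of broad, rounded leaflets (unit scale, centered)."""
    pts = []
    n_leaves = rng.integers(2, 4)
    base = rng.uniform(0, 2 * math.pi)
    for k in range(n_leaves):
        ang = base + 2 * math.pi * k / n_leaves + rng.normal(0, 0.2)
        lx, ly = 0.45 * math.cos(ang), 0.45 * math.sin(ang)
        for t in np.linspace(0, 2 * math.pi, 10, endpoint=False):
            r = 0.5 * (1 + 0.15 * math.sin(2 * t + rng.uniform(0, 1)))
            pts.append((lx + r * 0.55 * math.cos(t), ly + r * 0.45 * math.sin(t)))
    hull = sg.MultiPoint(pts).convex_hull
    ring = np.asarray(hull.exterior.coords[:-1])
    # soften the hull into a leafy outline
    jitter = rng.uniform(0.95, 1.05, size=len(ring))[:, None]
    return ring * jitter


def _grass_blades(rng: np.random.Generator) -> np.ndarray:
    """One thin, elongated, slightly curved blade (unit scale)."""
    length = rng.uniform(0.8, 1.0)
    width = rng.uniform(0.06, 0.14)
    curve = rng.uniform(-0.25, 0.25)
    ts = np.linspace(0, 1, 8)
    spine_x = ts * length
    spine_y = curve * ts ** 2
    left = np.stack([spine_x, spine_y + width * (1 - ts) / 2], axis=1)
    right = np.stack([spine_x, spine_y - width * (1 - ts) / 2], axis=1)[::-1]
    poly = np.vstack([left, right])
    ang = rng.uniform(0, 2 * math.pi)
    c, s = math.cos(ang), math.sin(ang)
    return (poly - poly.mean(axis=0)) @ np.array([[c, -s], [s, c]]).T


def _broadleaf_blob(rng: np.random.Generator) -> np.ndarray:
    """Lobed radial blob (unit scale, centered)."""
    n_lobes = rng.integers(3, 6)
    phase = rng.uniform(0, 2 * math.pi)
    ts = np.linspace(0, 2 * math.pi, 20, endpoint=False)
    r = 0.5 * (1 + 0.35 * np.sin(n_lobes * ts + phase) + rng.normal(0, 0.03, len(ts)))
    r = np.clip(r, 0.1, None)
    return np.stack([r * np.cos(ts), r * np.sin(ts)], axis=1)


_SHAPES = {
    0: _crop_leaf_cluster,   # crop-like: broad round leaves
    1: _grass_blades,        # grass-like: thin elongated blades
    2: _broadleaf_blob,      # broadleaf-weed-like: lobed blobs
}

# base palettes (RGB means); grass and crop overlap deliberately
_PALETTES = np.array(
    [
        [52, 110, 44],   # crop: dark green
        [95, 135, 38],   # grass: yellow-green
        [60, 125, 95],   # broadleaf: blue-green
    ],
    float,
)


def _instance_color(class_idx: int, separability: float, rng) -> np.ndarray:
    shared = _PALETTES.mean(axis=0)
    mean = shared + separability * (_PALETTES[class_idx] - shared)
    return np.clip(mean + rng.normal(0, 12, 3), 0, 255)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _background(h: int, w: int, rng) -> np.ndarray:
    base = np.array([98, 76, 58], float)  # dry soil
    img = np.tile(base, (h, w, 1))
    img += rng.normal(0, 9, (h, w, 3))
    # coarse soil texture
    coarse = rng.normal(0, 14, (max(h // 16, 1), max(w // 16, 1), 1))
    img += np.kron(coarse, np.ones((16, 16, 1)))[:h, :w]
    return img


def _apply_lighting(img: np.ndarray, spec: SceneSpec, rng) -> np.ndarray:
    h, w, _ = img.shape
    ys, xs = np.mgrid[0:h, 0:w]
    ang = rng.uniform(0, 2 * math.pi)
    ramp = (xs * math.cos(ang) + ys * math.sin(ang)) / max(h, w)
    strength = 0.5 if spec.lighting == "harsh" else 0.15
    img = img * (1.0 + strength * (ramp - ramp.mean()))[..., None]
    if spec.lighting == "harsh" and rng.uniform() < spec.specular_prob:
        for _ in range(rng.integers(1, 4)):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            sigma = rng.uniform(0.02, 0.06) * max(h, w)
            blob = np.exp(-((ys - cy) ** 2 + (xs - cx) ** 2) / (2 * sigma ** 2))
            img = img + 160.0 * blob[..., None]
    return img


def _allocate(proportions, n: int, rng) -> np.ndarray:
    """Exact largest-remainder allocation of `n` items, shuffled."""
    exact = np.asarray(proportions, float) * n
    counts = np.floor(exact).astype(int)
    for k in np.argsort(-(exact - counts), kind="stable")[: n - counts.sum()]:
        counts[k] += 1
    out = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(out)
    return out


def _sample_bins(spec: SceneSpec, rng) -> List[SizeBin]:
    return [_BINS[i] for i in _allocate(spec.size_quota, spec.n_instances, rng)]


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, AnnotationSet]:
    """Render one scene; returns (uint8 RGB image, single-image annotations)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    scale_to_image = (h * w) / (REFERENCE_RESOLUTION[0] * REFERENCE_RESOLUTION[1])

    img = _background(h, w, rng)

    placed: List[dict] = []
    bins = _sample_bins(spec, rng)
    class_alloc = _allocate(spec.class_mix, spec.n_instances, rng)
    # stratified free placement: jittered shuffled grid cells, so that
    # incidental overlap stays edge-like even in fully covered scenes
    side = max(int(math.ceil(math.sqrt(max(spec.n_instances, 1)))), 1)
    cells = [(r, c) for r in range(side) for c in range(side)]
    rng.shuffle(cells)
    for i in range(spec.n_instances):
        cls = int(class_alloc[i])
        lo, hi = _BIN_RANGES[bins[i]]
        # bbox area at image scale, sampled log-uniformly inside the bin
        # stay off the bin edges so occlusion shrinkage rarely demotes a bin
        lo_margin = 2.0 if bins[i] is SizeBin.LARGE else 1.3
        area_ref = math.exp(rng.uniform(math.log(lo * lo_margin), math.log(hi * 0.9)))
        target_area = max(area_ref * scale_to_image * spec.size_scale, 2.0)
        shape = _SHAPES[cls](rng)
        x1, y1 = shape.min(axis=0)
        x2, y2 = shape.max(axis=0)
        bbox_area = (x2 - x1) * (y2 - y1)
        shape = shape * math.sqrt(target_area / max(bbox_area, 1e-9))
        half = np.abs(shape).max() + 1
        if placed and rng.uniform() < spec.occlusion_rate:
            # partial edge overlap with a previously placed plant
            other = placed[int(rng.integers(len(placed)))]
            ang = rng.uniform(0, 2 * math.pi)
            dist = (half + other["half"]) * rng.uniform(0.7, 1.0)
            cx = other["center"][0] + dist * math.cos(ang)
            cy = other["center"][1] + dist * math.sin(ang)
        else:
            r, c = cells[i % len(cells)]
            cx = (c + rng.uniform(0.2, 0.8)) * w / side
            cy = (r + rng.uniform(0.2, 0.8)) * h / side
        cx = float(np.clip(cx, half, max(w - half, half)))
        cy = float(np.clip(cy, half, max(h - half, half)))
        poly = shape + np.array([cx, cy])
        # sub-2px² slivers (the thinnest blades) get a minimum physical
        # width so every instance covers at least one pixel when drawn
        pg = sg.Polygon(poly)
        if pg.is_valid and pg.area < 2.0:
            grown = pg.buffer(0.7, join_style=2)
            if grown.geom_type == "Polygon" and len(grown.exterior.coords) > 4:
                poly = np.asarray(grown.exterior.coords[:-1])
        placed.append(
            {
                "polygon": poly,
                "class_idx": cls,
                "center": (cx, cy),
                "half": half,
                "color": _instance_color(cls, spec.separability, rng),
            }
        )

    # canopy layering: larger plants sit behind, smaller ones in front,
    # so heavy occlusion does not silently erase the smallest instances
    placed.sort(key=lambda it: -sg.Polygon(it["polygon"]).area)

    # paint back-to-front
    for item in placed:
        poly = item["polygon"]
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        shade = 1.0 + rng.normal(0, 0.05)
        img[rr, cc] = item["color"] * shade
        # cheap vein/texture noise inside the plant
        img[rr, cc] += rng.normal(0, 6, (len(rr), 3))

    img = _apply_lighting(img, spec, rng)
    image = np.clip(img, 0, 255).astype(np.uint8)

    # visible polygons: subtract everything painted later (closer).
    # Occluders are eroded by ~1.5 px first: hairline overlaps (thin
    # grass blades crossing a leaf) do not cut an annotation in two,
    # matching how annotators treat sub-pixel-thin occlusion.
    instances: List[InstanceAnnotation] = []
    shapely_polys = []
    shrunk_polys = []
    for item in placed:
        p = sg.Polygon(item["polygon"])
        p = p if p.is_valid else p.buffer(0)
        shapely_polys.append(p)
        shrunk_polys.append(p.buffer(-2.0))
    frame = sg.box(0, 0, float(w), float(h))
    for i, item in enumerate(placed):
        visible = shapely_polys[i].intersection(frame)
        if i + 1 < len(placed):
            occluders = unary_union(shrunk_polys[i + 1 :])
            visible = visible.difference(occluders)
        if visible.is_empty:
            continue
        if visible.geom_type == "MultiPolygon":
            visible = max(visible.geoms, key=lambda g: g.area)
        if visible.geom_type != "Polygon" or visible.area < MIN_VISIBLE_AREA:
            continue
        coords = np.asarray(visible.exterior.coords[:-1])
        if len(coords) < 3:
            continue
        # an annotation must cover at least one pixel on the image grid,
        # otherwise its mask is empty and unmatchable
        rr, _cc = draw_polygon(coords[:, 1], coords[:, 0], shape=(h, w))
        if len(rr) == 0:
            continue
        instances.append(
            InstanceAnnotation(
                image_id=0,
                class_label=spec.classes[item["class_idx"]],
                polygon=coords,
            )
        )

    annotations = AnnotationSet(
        images=[ImageRecord(image_id=0, width=w, height=h, file_name="scene_000000.png")],
        instances=instances,
        classes=spec.classes,
    )
    return image, annotations


def generate_dataset(
    template: SceneSpec,
    n_images: int,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> Tuple[AnnotationSet, List[np.ndarray]]:
    """Generate `n_images` scenes with per-image seeds derived from `seed`.

    When `out_dir` is given, writes PNG images plus both annotation
    dialects (COCO-JSON and normalized-polygon text).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    from dataclasses import replace

    images: List[ImageRecord] = []
    pixel_list: List[np.ndarray] = []
    instances: List[InstanceAnnotation] = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_images)
    for i, child in enumerate(child_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        image, ann = generate_scene(replace(template, seed=sub_seed))
        im = ann.images[0]
        images.append(
            ImageRecord(
                image_id=i,
                width=im.width,
                height=im.height,
                file_name=f"scene_{i:06d}.png",
                pixels=image,
            )
        )
        pixel_list.append(image)
        for inst in ann.instances:
            instances.append(
                InstanceAnnotation(
                    image_id=i, class_label=inst.class_label, polygon=inst.polygon
                )
            )
    dataset = AnnotationSet(images=images, instances=instances, classes=template.classes)
    if out_dir is not None:
        _write_dataset(dataset, pixel_list, Path(out_dir))
    return dataset, pixel_list


def _write_dataset(dataset: AnnotationSet, pixels: List[np.ndarray], out_dir: Path) -> None:
    from PIL import Image

    from .annotations import write_coco, write_yolo_polygons

    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    for im, px in zip(dataset.images, pixels):
        Image.fromarray(px).save(out_dir / "images" / im.file_name)
    write_coco(dataset, out_dir / "annotations.json")
    write_yolo_polygons(dataset, out_dir)
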
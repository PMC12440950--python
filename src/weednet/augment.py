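"""Offline dataset augmentation.

The expansion is deterministic in structure: the output contains the
original images plus exactly one copy per method — rotation (±30°),
Gaussian pixel noise, translation (±10% of each side), vertical flip,
and brightness scaling — so instance counts multiply by exactly 6.
Rotation and translation transform the polygons (clipped to the image
frame); noise and brightness leave the geometry untouched.

Parameters that would push any instance (almost) fully outside the
frame are re-drawn; the magnitude shrinks over retries and collapses to
the identity in the limit, so no instance is ever lost.
"""

from __future__ import annotations

import math
from typing import Callable, List, Optional, Tuple

import numpy as np
import shapely.geometry as sg

from .annotations import AnnotationSet, ImageRecord, InstanceAnnotation

ROTATION_RANGE_DEG = 30.0
NOISE_SIGMA = 5.0          # uint8 grey levels, i.e. 5/255 of full scale
TRANSLATION_RANGE = 0.10   # fraction of each side
BRIGHTNESS_RANGE = (0.7, 1.3)
MIN_VISIBLE_AREA = 10.0    # px², below which params are re-drawn

AUGMENTATION_METHODS = ("rotation", "noise", "translation", "vflip", "brightness")


def _clip_polygon(poly: np.ndarray, width: int, height: int) -> Optional[np.ndarray]:
    """Intersect with the image frame; largest piece wins; None if gone."""
    shape = sg.Polygon(poly)
    if not shape.is_valid:
        shape = shape.buffer(0)
    frame = sg.box(0.0, 0.0, float(width), float(height))
    inter = shape.intersection(frame)
    if inter.is_empty:
        return None
    if inter.geom_type == "MultiPolygon":
        inter = max(inter.geoms, key=lambda p: p.area)
    if inter.geom_type != "Polygon" or inter.area <= 0:
        return None
    coords = np.asarray(inter.exterior.coords[:-1], float)
    if len(coords) < 3:
        return None
    return coords


def _affine_points(poly: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    homo = np.hstack([poly, np.ones((len(poly), 1))])
    return (homo @ matrix.T)[:, :2]


def _rotation_matrix(theta_deg: float, cx: float, cy: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array(
        [
            [c, -s, cx - c * cx + s * cy],
            [s, c, cy - s * cx - c * cy],
            [0, 0, 1.0],
        ]
    )


def _translation_matrix(tx: float, ty: float) -> np.ndarray:
    return np.array([[1.0, 0, tx], [0, 1.0, ty], [0, 0, 1.0]])


def _warp_image(pixels: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Inverse-map affine warp with bilinear sampling, constant fill."""
    from scipy.ndimage import affine_transform

    inv = np.linalg.inv(matrix)
    # affine_transform works in (row, col) = (y, x) order
    m = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset = np.array([inv[1, 2], inv[0, 2]])
    out = np.stack(
        [
            affine_transform(
                pixels[..., ch].astype(np.float32), m, offset=offset, order=1, cval=0.0
            )
            for ch in range(pixels.shape[-1])
        ],
        axis=-1,
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def vertical_flip_polygon(poly: np.ndarray, height: int) -> np.ndarray:
    out = poly.copy()
    out[:, 1] = height - out[:, 1]
    return out


def _geometric_copy(
    image: ImageRecord,
    instances: List[InstanceAnnotation],
    matrix_for: Callable[[float], np.ndarray],
    magnitudes: np.ndarray,
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Find a parameter magnitude that keeps every instance visible.

    Retries through progressively damped draws; magnitude 0 is the
    identity and always succeeds.
    """
    # a polygon that is already tiny must only stay roughly as visible
    thresholds = [
        min(MIN_VISIBLE_AREA, 0.8 * inst.polygon_area) for inst in instances
    ]
    for attempt, mag in enumerate(magnitudes):
        matrix = matrix_for(float(mag))
        polys = []
        ok = True
        for inst, thr in zip(instances, thresholds):
            moved = _affine_points(inst.polygon, matrix)
            clipped = _clip_polygon(moved, image.width, image.height)
            if clipped is None or sg.Polygon(clipped).area < thr:
                ok = False
                break
            polys.append(clipped)
        if ok:
            return matrix, polys
    raise AssertionError("identity transform should always keep instances")


def augment_set(a: AnnotationSet, seed: int = 0) -> AnnotationSet:
    """Original set plus one transformed copy per augmentation method."""
    rng = np.random.default_rng(seed)
    next_id = max((im.image_id for im in a.images), default=-1) + 1
    images: List[ImageRecord] = list(a.images)
    instances: List[InstanceAnnotation] = list(a.instances)

    for method in AUGMENTATION_METHODS:
        for im in a.images:
            insts = a.instances_of(im.image_id)
            new_im = ImageRecord(
                image_id=next_id,
                width=im.width,
                height=im.height,
                file_name=(
                    f"{im.file_name.rsplit('.', 1)[0]}_{method}.png" if im.file_name else None
                ),
            )
            if method == "rotation":
                draws = rng.uniform(-1, 1, 16) * ROTATION_RANGE_DEG
                draws *= 0.5 ** np.arange(16)  # damp toward identity
                cx, cy = im.width / 2.0, im.height / 2.0
                matrix, polys = _geometric_copy(
                    im, insts, lambda m: _rotation_matrix(m, cx, cy), draws
                )
                if im.pixels is not None:
                    new_im.pixels = _warp_image(im.pixels, matrix)
            elif method == "translation":
                dx = rng.uniform(-1, 1, 16) * TRANSLATION_RANGE * im.width
                dy = rng.uniform(-1, 1, 16) * TRANSLATION_RANGE * im.height
                damp = 0.5 ** np.arange(16)
                pairs = np.stack([dx * damp, dy * damp], axis=1)

                def tmat(_m, _pairs=pairs):
                    return _translation_matrix(*_pairs[int(_m)])

                matrix, polys = _geometric_copy(
                    im, insts, tmat, np.arange(len(pairs))
                )
                if im.pixels is not None:
                    new_im.pixels = _warp_image(im.pixels, matrix)
            elif method == "vflip":
                polys = [vertical_flip_polygon(i.polygon, im.height) for i in insts]
                if im.pixels is not None:
                    new_im.pixels = im.pixels[::-1].copy()
            elif method == "noise":
                polys = [i.polygon.copy() for i in insts]
                if im.pixels is not None:
                    noisy = im.pixels.astype(np.float32) + rng.normal(
                        0.0, NOISE_SIGMA, im.pixels.shape
                    )
                    new_im.pixels = np.clip(noisy, 0, 255).astype(np.uint8)
            elif method == "brightness":
                polys = [i.polygon.copy() for i in insts]
                if im.pixels is not None:
                    factor = rng.uniform(*BRIGHTNESS_RANGE)
                    new_im.pixels = np.clip(
                        im.pixels.astype(np.float32) * factor, 0, 255
                    ).astype(np.uint8)
            images.append(new_im)
            for inst, poly in zip(insts, polys):
                instances.append(
                    InstanceAnnotation(
                        image_id=next_id, class_label=inst.class_label, polygon=poly
                    )
                )
            next_id += 1

    return AnnotationSet(images=images, instances=instances, classes=a.classes)
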
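import numpy as np
import pytest

from weednet.annotations import AnnotationSet, ImageRecord, InstanceAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def triangle(cx: float, cy: float, r: float = 3.0) -> np.ndarray:
    """A small triangle polygon centered at (cx, cy)."""
    return np.array([[cx - r, cy + r], [cx + r, cy + r], [cx, cy - r]], float)


def counts_fixture(per_class_counts, classes, image_size=128, per_image=250, id_offset=0):
    """Build an annotation set holding exact per-class instance counts.

    Instances are small triangles kept inside the central region of each
    image so that every geometric transform can preserve them.
    """
    total = sum(per_class_counts.values())
    n_images = max((total + per_image - 1) // per_image, 1)
    images = [
        ImageRecord(image_id=id_offset + i, width=image_size, height=image_size)
        for i in range(n_images)
    ]
    instances = []
    labels = [c for c, n in per_class_counts.items() for _ in range(n)]
    lo, hi = 0.25 * image_size, 0.75 * image_size
    grid = int(np.ceil(np.sqrt(per_image)))
    step = (hi - lo) / grid
    for k, label in enumerate(labels):
        img_idx = k // per_image
        slot = k % per_image
        cx = lo + (slot % grid + 0.5) * step
        cy = lo + (slot // grid + 0.5) * step
        instances.append(
            InstanceAnnotation(
                image_id=id_offset + img_idx,
                class_label=label,
                polygon=triangle(cx, cy, r=min(step * 0.4, 3.0)),
            )
        )
    return AnnotationSet(images=images, instances=instances, classes=tuple(classes))


@pytest.fixture(scope="session")
def tiny_scene_dataset():
    """A small rendered dataset shared by evaluation/training tests."""
    from weednet.scenes import SceneSpec, generate_dataset

    spec = SceneSpec(
        image_size=(128, 128),
        n_instances=5,
        occlusion_rate=0.2,
        size_quota=(0.0, 0.1, 0.5, 0.4),
    )
    dataset, pixels = generate_dataset(spec, 4, seed=11)
    return dataset, pixels
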
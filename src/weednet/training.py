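"""Training loop, inference and checkpoint round-trips.

The recipe follows the standard single-stage-detector defaults: SGD
with momentum 0.937 and weight decay 5e-4, linear warmup followed by
cosine decay, no pretrained weights. Offline 6× augmentation (see
:mod:`weednet.augment`) is the expected dataset-expansion path; the
loop itself performs no online augmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotations import AnnotationSet
from .detections import DetectionList
from .loss import BatchTargets, compute_loss
from .metrics import evaluate, rasterize_polygon
from .model import (
    ModelConfig,
    SegmentationModel,
    build_model,
    load_checkpoint,
    postprocess,
    save_checkpoint,
)
from .nn import no_grad
from .nn.autograd import Tensor
from .nn.optim import SGD, WarmupCosineSchedule


@dataclass
class TrainConfig:
    epochs: int = 600
    batch_size: int = 64
    image_size: int = 640
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_steps: int = 25
    grad_clip_norm: float = 10.0
    seed: int = 0
    max_iterations: Optional[int] = None  # overrides epochs when set
    val_interval: int = 0  # epochs between val evaluations; 0 = never
    out_dir: Optional[Path] = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _image_tensor(pixels: np.ndarray) -> np.ndarray:
    return (pixels.astype(np.float32) / 255.0).transpose(2, 0, 1)


def prepare_samples(dataset: AnnotationSet, proto_stride: int = 8) -> List[dict]:
    """Convert an annotation set with pixel data into training samples."""
    samples = []
    for im in dataset.images:
        if im.pixels is None:
            raise ValueError(f"image {im.image_id} has no pixel data")
        insts = dataset.instances_of(im.image_id)
        hp, wp = im.height // proto_stride, im.width // proto_stride
        boxes, classes, masks = [], [], []
        for inst in insts:
            boxes.append(inst.bbox)
            classes.append(dataset.class_index(inst.class_label))
            masks.append(
                rasterize_polygon(inst.polygon / proto_stride, hp, wp).astype(np.float32)
            )
        samples.append(
            {
                "image_id": im.image_id,
                "image": _image_tensor(im.pixels),
                "boxes": np.asarray(boxes, np.float32).reshape(-1, 4),
                "classes": np.asarray(classes, np.int64),
                "masks": np.stack(masks) if masks else np.zeros((0, hp, wp), np.float32),
            }
        )
    return samples


def _collate(batch: List[dict]) -> Tuple[Tensor, BatchTargets]:
    images = Tensor(np.stack([s["image"] for s in batch]))
    targets = BatchTargets(
        boxes=[s["boxes"] for s in batch],
        classes=[s["classes"] for s in batch],
        masks=[s["masks"] for s in batch],
    )
    return images, targets


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    model: SegmentationModel,
    train_set: AnnotationSet,
    cfg: TrainConfig,
    val_set: Optional[AnnotationSet] = None,
) -> Dict:
    """Train in place; returns the history log (and writes a checkpoint
    to ``cfg.out_dir`` when given)."""
    if not train_set.images:
        raise ValueError("training set is empty")
    samples = prepare_samples(train_set)
    rng = np.random.default_rng(cfg.seed)
    n = len(samples)
    steps_per_epoch = max(math.ceil(n / cfg.batch_size), 1)
    total_steps = (
        cfg.max_iterations
        if cfg.max_iterations is not None
        else cfg.epochs * steps_per_epoch
    )
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    sched = WarmupCosineSchedule(opt, cfg.lr, total_steps, cfg.warmup_steps)
    history: Dict = {"epochs": [], "config": {"lr": cfg.lr, "batch_size": cfg.batch_size}}
    model.train()
    step = 0
    epoch = 0
    while step < total_steps:
        order = rng.permutation(n)
        epoch_log = {"total": 0.0, "box": 0.0, "cls": 0.0, "dfl": 0.0, "seg": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            if step >= total_steps:
                break
            batch = [samples[i] for i in order[start : start + cfg.batch_size]]
            images, targets = _collate(batch)
            outs, protos = model(images)
            loss = compute_loss(outs, protos, targets, reg_max=model.cfg.reg_max)
            model.zero_grad()
            loss.total.backward()
            if cfg.grad_clip_norm:
                _clip_grad_norm(model.parameters(), cfg.grad_clip_norm)
            sched.step()
            opt.step()
            for k, v in loss.as_dict().items():
                epoch_log[k] += v
            n_batches += 1
            step += 1
        if n_batches:
            for k in epoch_log:
                epoch_log[k] /= n_batches
        epoch += 1
        entry = {"epoch": epoch, "step": step, **epoch_log}
        if val_set is not None and cfg.val_interval and epoch % cfg.val_interval == 0:
            preds = predict_dataset(model, val_set)
            entry["val"] = evaluate(preds, val_set)
        history["epochs"].append(entry)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out / "model.npz", model, extra={"history_epochs": len(history["epochs"])})
        history["checkpoint"] = str(out / "model.npz")
    return history


def _clip_grad_norm(params, max_norm: float) -> None:
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _letterbox(pixels: np.ndarray, multiple: int = 32) -> Tuple[np.ndarray, Tuple[int, int]]:
    h, w = pixels.shape[:2]
    ph = (multiple - h % multiple) % multiple
    pw = (multiple - w % multiple) % multiple
    if ph or pw:
        pixels = np.pad(pixels, ((0, ph), (0, pw), (0, 0)))
    return pixels, (h, w)


def predict(
    model: SegmentationModel,
    images: Sequence[np.ndarray],
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.7,
    image_ids: Optional[Sequence[int]] = None,
) -> List[DetectionList]:
    """Run inference on uint8 RGB arrays; one DetectionList per image,
    in input order. Non-multiple-of-32 sizes are zero-padded (letterbox)
    and outputs mapped back."""
    model.eval()
    results = []
    for i, px in enumerate(images):
        padded, (h, w) = _letterbox(px)
        x = Tensor(_image_tensor(padded)[None])
        with no_grad():
            outs, protos = model(x)
        iid = image_ids[i] if image_ids is not None else i
        det = postprocess(
            outs,
            protos,
            image_size=padded.shape[:2],
            conf_threshold=conf_threshold,
            iou_threshold=iou_threshold,
            image_ids=[iid],
            reg_max=model.cfg.reg_max,
        )[0]
        if (h, w) != padded.shape[:2]:
            for d in det:
                d.box = np.clip(d.box, [0, 0, 0, 0], [w, h, w, h])
                if d.mask is not None:
                    d.mask = d.mask[:h, :w]
        results.append(det)
    return results


def predict_dataset(
    model: SegmentationModel,
    dataset: AnnotationSet,
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.7,
) -> DetectionList:
    out = DetectionList()
    ids = [im.image_id for im in dataset.images]
    pixels = [dataset.image(i).pixels for i in ids]
    for det in predict(model, pixels, conf_threshold, iou_threshold, image_ids=ids):
        out.extend(det)
    return out


def render_overlay(pixels: np.ndarray, detections: DetectionList,
                   class_names: Sequence[str]) -> np.ndarray:
    """Draw masks, boxes and labels onto a copy of the image."""
    colors = np.array([[228, 60, 60], [60, 160, 228], [240, 200, 60],
                       [90, 220, 120], [200, 90, 220]], np.float32)
    img = pixels.astype(np.float32).copy()
    for d in detections:
        color = colors[d.class_id % len(colors)]
        if d.mask is not None:
            img[d.mask] = 0.55 * img[d.mask] + 0.45 * color
        x1, y1, x2, y2 = (int(round(v)) for v in d.box)
        x1, y1 = max(x1, 0), max(y1, 0)
        x2 = min(x2, img.shape[1] - 1)
        y2 = min(y2, img.shape[0] - 1)
        img[y1 : y2 + 1, [x1, x2]] = color
        img[[y1, y2], x1 : x2 + 1] = color
    return np.clip(img, 0, 255).astype(np.uint8)
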
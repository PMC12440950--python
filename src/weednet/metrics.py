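"""Dual evaluation stack: instance-level P/R/AP/mAP and pixel-level mIoU/mAcc.

Instance metrics follow the COCO convention: per-class greedy matching
in descending confidence order (highest-IoU unmatched ground truth
wins, at or above the threshold), average precision by 101-point
interpolation of the precision–recall curve, mAP50 at IoU 0.5 and
mAP50:95 averaged over T = {0.50, 0.55, …, 0.95}.

Pixel metrics collapse instances to class label grids (predicted
overlaps resolved by confidence), aggregate per-class TP/FP/FN counts
over the whole set, and average per class:

    mAcc = mean_i TP_i / (TP_i + FN_i)
    mIoU = mean_i TP_i / (TP_i + FN_i + FP_i)

Background is not a class; classes absent from both prediction and
truth are excluded from the means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import polygon as draw_polygon

from .annotations import AnnotationSet, InstanceAnnotation
from .detections import Detection, DetectionList

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))  # |T| = 10


# ---------------------------------------------------------------------------
# IoU primitives
# ---------------------------------------------------------------------------

def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes; 0 if empty."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def rasterize_polygon(poly: np.ndarray, height: int, width: int) -> np.ndarray:
    """Fill a polygon onto a (height, width) boolean grid."""
    mask = np.zeros((height, width), bool)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(height, width))
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass
class EvalCounts:
    """Instance tallies per class plus per-class pixel confusion counts."""

    tp: Dict[str, int] = field(default_factory=dict)
    fp: Dict[str, int] = field(default_factory=dict)
    fn: Dict[str, int] = field(default_factory=dict)
    pixel_tp: Dict[str, int] = field(default_factory=dict)
    pixel_fp: Dict[str, int] = field(default_factory=dict)
    pixel_fn: Dict[str, int] = field(default_factory=dict)

    def totals(self) -> Tuple[int, int, int]:
        return (
            sum(self.tp.values()),
            sum(self.fp.values()),
            sum(self.fn.values()),
        )


def _truth_masks(truth: AnnotationSet, kind: str) -> Dict[int, List[dict]]:
    """Per-image ground-truth entries with rasterized masks or boxes."""
    by_image: Dict[int, List[dict]] = {im.image_id: [] for im in truth.images}
    sizes = {im.image_id: (im.height, im.width) for im in truth.images}
    for inst in truth.instances:
        h, w = sizes[inst.image_id]
        entry = {"class": inst.class_label, "box": inst.bbox, "matched": False}
        if kind == "mask":
            entry["mask"] = rasterize_polygon(inst.polygon, h, w)
        by_image[inst.image_id].append(entry)
    return by_image


def _detection_iou(det: Detection, entry: dict, kind: str) -> float:
    if kind == "box":
        return box_iou(det.box, entry["box"])
    if det.mask is None:
        raise ValueError("mask matching requested but detection has no mask")
    return mask_iou(det.mask, entry["mask"])


def match_and_count(
    preds: DetectionList,
    truth: AnnotationSet,
    t: float,
    kind: str = "mask",
) -> EvalCounts:
    """Greedy confidence-ordered matching at IoU threshold `t`.

    Each ground truth may be claimed once; the unmatched leftovers are
    false negatives, unmatched predictions false positives.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("IoU threshold must lie in (0, 1)")
    counts = EvalCounts()
    for c in truth.classes:
        counts.tp[c] = counts.fp[c] = counts.fn[c] = 0
    gts = _truth_masks(truth, kind)
    for det in preds.sorted_by_confidence():
        label = truth.classes[det.class_id]
        candidates = [
            e for e in gts.get(det.image_id, []) if e["class"] == label and not e["matched"]
        ]
        best, best_iou = None, 0.0
        for e in candidates:
            iou = _detection_iou(det, e, kind)
            if iou >= t and iou > best_iou:
                best, best_iou = e, iou
        if best is not None:
            best["matched"] = True
            counts.tp[label] += 1
        else:
            counts.fp[label] += 1
    for entries in gts.values():
        for e in entries:
            if not e["matched"]:
                counts.fn[e["class"]] += 1
    return counts


def precision_recall(counts: EvalCounts) -> Tuple[float, float]:
    """Aggregate P = TP/(TP+FP) and R = TP/(TP+FN); 0/0 → 0."""
    tp, fp, fn = counts.totals()
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def _score_class(
    preds: DetectionList, truth: AnnotationSet, class_label: str, t: float, kind: str
) -> Tuple[np.ndarray, int]:
    """Confidence-ordered TP flags for one class, plus the truth count."""
    cls_id = truth.class_index(class_label)
    dets = [d for d in preds.sorted_by_confidence() if d.class_id == cls_id]
    gts = _truth_masks(truth, kind)
    n_truth = sum(1 for es in gts.values() for e in es if e["class"] == class_label)
    flags = np.zeros(len(dets), bool)
    for i, det in enumerate(dets):
        best, best_iou = None, 0.0
        for e in gts.get(det.image_id, []):
            if e["class"] != class_label or e["matched"]:
                continue
            iou = _detection_iou(det, e, kind)
            if iou >= t and iou > best_iou:
                best, best_iou = e, iou
        if best is not None:
            best["matched"] = True
            flags[i] = True
    return flags, n_truth


def average_precision(
    preds: DetectionList,
    truth: AnnotationSet,
    class_label: str,
    t: float = 0.5,
    kind: str = "mask",
) -> Optional[float]:
    """101-point interpolated AP for one class; None if no ground truth."""
    flags, n_truth = _score_class(preds, truth, class_label, t, kind)
    if n_truth == 0:
        return None
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_truth
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope, then sample at 101 evenly spaced recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        idx = np.searchsorted(recall, r, side="left")
        ap += env[idx] if idx < len(env) else 0.0
    return ap / 101.0


def mean_average_precision(
    preds: DetectionList,
    truth: AnnotationSet,
    t: float = 0.5,
    kind: str = "mask",
) -> float:
    """Class-mean AP at one IoU threshold (classes without truth skipped)."""
    aps = [average_precision(preds, truth, c, t, kind) for c in truth.classes]
    aps = [a for a in aps if a is not None]
    return float(np.mean(aps)) if aps else 0.0


def map50(preds, truth, kind: str = "mask") -> float:
    return mean_average_precision(preds, truth, 0.5, kind)


def map50_95(preds, truth, kind: str = "mask") -> float:
    return float(
        np.mean([mean_average_precision(preds, truth, t, kind) for t in IOU_THRESHOLDS])
    )


# ---------------------------------------------------------------------------
# pixel metrics
# ---------------------------------------------------------------------------

def _label_grid_from_truth(truth: AnnotationSet, image_id: int) -> np.ndarray:
    im = truth.image(image_id)
    grid = np.full((im.height, im.width), -1, np.int32)
    for inst in truth.instances_of(image_id):
        mask = rasterize_polygon(inst.polygon, im.height, im.width)
        grid[mask] = truth.class_index(inst.class_label)
    return grid


def _label_grid_from_preds(
    preds: DetectionList, height: int, width: int
) -> np.ndarray:
    grid = np.full((height, width), -1, np.int32)
    # ascending confidence so the most confident instance wins overlaps
    for det in sorted(preds, key=lambda d: d.confidence):
        if det.mask is None:
            raise ValueError("pixel metrics need detection masks")
        if det.mask.shape != (height, width):
            raise ValueError(
                f"mask grid {det.mask.shape} does not match image {(height, width)}"
            )
        grid[det.mask] = det.class_id
    return grid


def pixel_metrics(
    preds: DetectionList, truth: AnnotationSet
) -> Tuple[float, float, EvalCounts]:
    """Class-averaged pixel accuracy (mAcc) and IoU (mIoU) over the set."""
    counts = EvalCounts()
    for c in truth.classes:
        counts.pixel_tp[c] = counts.pixel_fp[c] = counts.pixel_fn[c] = 0
    for im in truth.images:
        tgrid = _label_grid_from_truth(truth, im.image_id)
        pgrid = _label_grid_from_preds(preds.for_image(im.image_id), im.height, im.width)
        for ci, c in enumerate(truth.classes):
            tmask = tgrid == ci
            pmask = pgrid == ci
            counts.pixel_tp[c] += int(np.logical_and(tmask, pmask).sum())
            counts.pixel_fp[c] += int(np.logical_and(~tmask, pmask).sum())
            counts.pixel_fn[c] += int(np.logical_and(tmask, ~pmask).sum())
    accs, ious = [], []
    for c in truth.classes:
        tp, fp, fn = counts.pixel_tp[c], counts.pixel_fp[c], counts.pixel_fn[c]
        if tp + fp + fn == 0:
            continue  # class absent everywhere
        accs.append(tp / (tp + fn) if tp + fn else 0.0)
        ious.append(tp / (tp + fn + fp))
    macc = float(np.mean(accs)) if accs else 0.0
    miou = float(np.mean(ious)) if ious else 0.0
    return macc, miou, counts


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def evaluate(preds: DetectionList, truth: AnnotationSet) -> Dict[str, float]:
    """The full metric report with the standard flat keys."""
    report: Dict[str, float] = {}
    for kind in ("box", "mask"):
        counts = match_and_count(preds, truth, 0.5, kind)
        p, r = precision_recall(counts)
        report[f"P_{kind}"] = p
        report[f"R_{kind}"] = r
        report[f"mAP50_{kind}"] = map50(preds, truth, kind)
        report[f"mAP50_95_{kind}"] = map50_95(preds, truth, kind)
    macc, miou, _ = pixel_metrics(preds, truth)
    report["mIoU"] = miou
    report["mAcc"] = macc
    return report


def write_report(report: Dict[str, float], path) -> None:
    Path(path).write_text(json.dumps({k: float(v) for k, v in report.items()}, indent=2))


# ---------------------------------------------------------------------------
# COCO-style results JSON (detections with uncompressed RLE masks)
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> dict:
    """Column-major uncompressed run-length encoding, starting with zeros."""
    flat = np.asarray(mask, bool).flatten(order="F")
    if flat.size == 0:
        return {"size": list(mask.shape), "counts": [0]}
    changes = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    runs = np.diff(np.concatenate([[0], changes, [flat.size]])).tolist()
    if flat[0]:
        runs = [0] + runs
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": runs}


def _rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def write_detections_json(preds: DetectionList, path) -> None:
    doc = []
    for d in preds:
        x1, y1, x2, y2 = (float(v) for v in d.box)
        entry = {
            "image_id": d.image_id,
            "category_id": d.class_id + 1,
            "score": d.confidence,
            "bbox": [x1, y1, x2 - x1, y2 - y1],
        }
        if d.mask is not None:
            entry["segmentation"] = _rle_encode(d.mask)
        doc.append(entry)
    Path(path).write_text(json.dumps(doc))


def read_detections_json(path) -> DetectionList:
    doc = json.loads(Path(path).read_text())
    out = DetectionList()
    for entry in doc:
        x, y, w, h = entry["bbox"]
        mask = _rle_decode(entry["segmentation"]) if "segmentation" in entry else None
        out.append(
            Detection(
                image_id=entry["image_id"],
                class_id=entry["category_id"] - 1,
                confidence=entry["score"],
                box=np.array([x, y, x + w, y + h]),
                mask=mask,
            )
        )
    return out


def ground_truth_detections(truth: AnnotationSet, confidence: float = 1.0) -> DetectionList:
    """Turn annotations into perfect-score detections (self-evaluation)."""
    out = DetectionList()
    sizes = {im.image_id: (im.height, im.width) for im in truth.images}
    for inst in truth.instances:
        h, w = sizes[inst.image_id]
        out.append(
            Detection(
                image_id=inst.image_id,
                class_id=truth.class_index(inst.class_label),
                confidence=confidence,
                box=np.asarray(inst.bbox, float),
                mask=rasterize_polygon(inst.polygon, h, w),
            )
        )
    return out
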
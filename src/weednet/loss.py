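"""Four-term detection/segmentation loss with task-aligned assignment.

Components (anchor-free, one anchor per grid cell at strides 8/16/32):

* ``box`` — complete-IoU loss on decoded boxes of positive anchors;
* ``cls`` — binary cross-entropy of class scores against soft
  task-aligned targets;
* ``dfl`` — distribution-focal loss: cross-entropy of the discretized
  per-side offset against its two neighbouring bins;
* ``seg`` — per-positive binary cross-entropy of the assembled
  prototype mask against the instance mask, restricted to the ground
  truth box and normalized by its area.

Assignment is task-aligned top-k (k=10): candidate anchors must lie
inside the ground-truth box, are ranked by score^0.5 · IoU^6, and an
anchor claimed by several boxes goes to the highest-IoU one.

Total = 7.5·box + 0.5·cls + 1.5·dfl + 1.0·seg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import anchor_points
from .nn import functional as F
from .nn.autograd import Tensor, no_grad

LOSS_WEIGHTS = {"box": 7.5, "cls": 0.5, "dfl": 1.5, "seg": 1.0}
TAL_TOPK = 10
TAL_ALPHA = 0.5
TAL_BETA = 6.0


@dataclass
class LossBreakdown:
    total: Tensor
    box: float
    cls: float
    dfl: float
    seg: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "total": float(self.total.data),
            "box": self.box,
            "cls": self.cls,
            "dfl": self.dfl,
            "seg": self.seg,
        }


@dataclass
class BatchTargets:
    """Ground truth for one batch: per-image boxes, classes and masks."""

    boxes: List[np.ndarray]      # (n_i, 4) pixel xyxy
    classes: List[np.ndarray]    # (n_i,) int
    masks: List[np.ndarray]      # (n_i, Hp, Wp) float {0,1} at proto stride


def _flatten_outputs(raw_outputs, reg_max: int, strides: Sequence[int]):
    """Concatenate per-level maps into (B, A, ·) tensors + anchor geometry."""
    dist_parts, cls_parts, coef_parts = [], [], []
    anchors, stride_arr = [], []
    for out, stride in zip(raw_outputs, strides):
        b, c4, h, w = out["box"].shape
        dist_parts.append(F.transpose(out["box"].reshape(b, c4, h * w), (0, 2, 1)))
        nc = out["cls"].shape[1]
        cls_parts.append(F.transpose(out["cls"].reshape(b, nc, h * w), (0, 2, 1)))
        nm = out["mcoef"].shape[1]
        coef_parts.append(F.transpose(out["mcoef"].reshape(b, nm, h * w), (0, 2, 1)))
        anchors.append(anchor_points(h, w, stride))
        stride_arr.append(np.full(h * w, stride, np.float32))
    dist = F.concat(dist_parts, axis=1)  # (B, A, 4*rm)
    a = dist.shape[1]
    dist = dist.reshape(dist.shape[0], a, 4, reg_max)
    return (
        dist,
        F.concat(cls_parts, axis=1),
        F.concat(coef_parts, axis=1),
        np.concatenate(anchors),
        np.concatenate(stride_arr),
    )


def _decode_differentiable(dist: Tensor, anchors: np.ndarray, stride_arr: np.ndarray) -> Tensor:
    """Expected-bin decoding that keeps the graph: (B, A, 4) xyxy boxes."""
    reg_max = dist.shape[-1]
    prob = F.softmax(dist, axis=-1)
    bins = np.arange(reg_max, dtype=np.float32)
    offsets = (prob * bins).sum(axis=-1) * stride_arr[None, :, None]  # (B,A,4) ltrb
    ax = anchors[None, :, 0:1]  # (1, A, 1)
    ay = anchors[None, :, 1:2]
    x1 = F.sub(ax, offsets[:, :, 0:1])
    y1 = F.sub(ay, offsets[:, :, 1:2])
    x2 = F.add(ax, offsets[:, :, 2:3])
    y2 = F.add(ay, offsets[:, :, 3:4])
    return F.concat([x1, y1, x2, y2], axis=2)


def _iou_xyxy_np(boxes: np.ndarray, gts: np.ndarray) -> np.ndarray:
    """(A,4) x (n,4) pairwise IoU, plain numpy."""
    lt = np.maximum(boxes[:, None, :2], gts[None, :, :2])
    rb = np.minimum(boxes[:, None, 2:], gts[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(boxes[:, 2] - boxes[:, 0], 0, None) * np.clip(boxes[:, 3] - boxes[:, 1], 0, None)
    area_b = (gts[:, 2] - gts[:, 0]) * (gts[:, 3] - gts[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-9), 0.0)


def assign_targets(
    scores: np.ndarray,       # (A, nc) sigmoid class scores
    decoded: np.ndarray,      # (A, 4) decoded boxes
    anchors: np.ndarray,      # (A, 2)
    gt_boxes: np.ndarray,     # (n, 4)
    gt_classes: np.ndarray,   # (n,)
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Task-aligned assignment for one image.

    Returns (fg_mask (A,), gt_index (A,), target_scores (A, nc)).
    """
    a, nc = scores.shape
    n = len(gt_boxes)
    fg = np.zeros(a, bool)
    gt_idx = np.full(a, -1, np.int64)
    tscores = np.zeros((a, nc), np.float32)
    if n == 0:
        return fg, gt_idx, tscores
    inside = (
        (anchors[:, 0:1] > gt_boxes[None, :, 0])
        & (anchors[:, 0:1] < gt_boxes[None, :, 2])
        & (anchors[:, 1:2] > gt_boxes[None, :, 1])
        & (anchors[:, 1:2] < gt_boxes[None, :, 3])
    )  # (A, n)
    ious = _iou_xyxy_np(decoded, gt_boxes)
    cls_score = scores[:, gt_classes]  # (A, n)
    metric = (cls_score ** TAL_ALPHA) * (ious ** TAL_BETA)
    metric = np.where(inside, metric, 0.0)
    # top-k anchors per ground truth
    mask = np.zeros_like(inside)
    k = min(TAL_TOPK, a)
    top = np.argpartition(-metric, k - 1, axis=0)[:k]
    for g in range(n):
        sel = top[:, g]
        sel = sel[metric[sel, g] > 0]
        mask[sel, g] = True
    # resolve anchors claimed by several boxes: highest IoU wins
    multi = mask.sum(axis=1)
    claimed = multi > 0
    best_gt = np.argmax(np.where(mask, ious, -1.0), axis=1)
    fg[claimed] = True
    gt_idx[claimed] = best_gt[claimed]
    # soft targets: per-gt normalized alignment metric scaled by best IoU
    pos_metric = np.zeros(a, np.float32)
    pos_metric[claimed] = metric[claimed, best_gt[claimed]]
    for g in range(n):
        sel = fg & (gt_idx == g)
        if not sel.any():
            continue
        m_max = metric[sel, g].max()
        iou_max = ious[sel, g].max()
        tscores[sel, gt_classes[g]] = (
            metric[sel, g] / max(m_max, 1e-9) * iou_max
        ).astype(np.float32)
    return fg, gt_idx, tscores


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU of matched box pairs; pred (P,4) tensor, target (P,4)."""
    tx1, ty1, tx2, ty2 = target[:, 0], target[:, 1], target[:, 2], target[:, 3]
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    iw = F.clip(F.minimum(px2, tx2) - F.maximum(px1, tx1), 0.0, None)
    ih = F.clip(F.minimum(py2, ty2) - F.maximum(py1, ty1), 0.0, None)
    inter = iw * ih
    area_p = F.clip(px2 - px1, 0.0, None) * F.clip(py2 - py1, 0.0, None)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter
    iou = inter / F.clip(union, 1e-7, None)
    # enclosing-box diagonal
    cw = F.maximum(px2, tx2) - F.minimum(px1, tx1)
    ch = F.maximum(py2, ty2) - F.minimum(py1, ty1)
    c2 = cw * cw + ch * ch + 1e-7
    rho2 = ((px1 + px2 - tx1 - tx2) ** 2.0 + (py1 + py2 - ty1 - ty2) ** 2.0) * 0.25
    v_t = np.arctan((tx2 - tx1) / np.maximum(ty2 - ty1, 1e-7))
    v_p = F.arctan((px2 - px1) / F.clip(py2 - py1, 1e-7, None))
    dv = F.sub(v_t, v_p)
    v = dv * dv * (4.0 / math.pi ** 2)
    with no_grad():
        alpha = v.data / np.maximum(1.0 - iou.data + v.data, 1e-7)
    return iou - rho2 / c2 - v * alpha


def compute_loss(
    raw_outputs,
    protos: Tensor,
    targets: BatchTargets,
    reg_max: int = 16,
    strides: Sequence[int] = (8, 16, 32),
    weights: Optional[Dict[str, float]] = None,
) -> LossBreakdown:
    weights = weights or LOSS_WEIGHTS
    dist, cls_logits, coefs, anchors, stride_arr = _flatten_outputs(
        raw_outputs, reg_max, strides
    )
    batch, a, nc = cls_logits.shape
    decoded = _decode_differentiable(dist, anchors, stride_arr)

    # ---- assignment (decision is gradient-free) --------------------------
    with no_grad(), np.errstate(over="ignore"):
        scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data))
        decoded_np = decoded.data
    fg_list, gidx_list, tscore_list = [], [], []
    for b in range(batch):
        fg, gidx, tsc = assign_targets(
            scores_np[b], decoded_np[b], anchors,
            np.asarray(targets.boxes[b], np.float32).reshape(-1, 4),
            np.asarray(targets.classes[b], np.int64).reshape(-1),
        )
        fg_list.append(fg)
        gidx_list.append(gidx)
        tscore_list.append(tsc)
    tscores = np.stack(tscore_list)  # (B, A, nc)
    score_sum = max(float(tscores.sum()), 1.0)

    # ---- classification ---------------------------------------------------
    cls_loss = F.bce_with_logits(cls_logits, tscores, reduction="sum") * (1.0 / score_sum)

    # ---- localization -----------------------------------------------------
    bi, ai = np.nonzero(np.stack(fg_list))
    n_pos = len(bi)
    if n_pos:
        # per-positive gt arrays in (bi, ai) order
        gt_box = np.stack(
            [targets.boxes[b][gidx_list[b][a_]] for b, a_ in zip(bi, ai)]
        ).astype(np.float32)
        w_pos = tscores[bi, ai].sum(axis=1).astype(np.float32)
        pred_pos = decoded[bi, ai]  # (P, 4)
        ciou = _ciou(pred_pos, gt_box)
        box_loss = ((1.0 - ciou) * w_pos).sum() * (1.0 / score_sum)

        # ---- distribution-focal -------------------------------------------
        st = stride_arr[ai]
        ltrb = np.stack(
            [
                anchors[ai, 0] - gt_box[:, 0],
                anchors[ai, 1] - gt_box[:, 1],
                gt_box[:, 2] - anchors[ai, 0],
                gt_box[:, 3] - anchors[ai, 1],
            ],
            axis=1,
        ) / st[:, None]
        ltrb = np.clip(ltrb, 0, reg_max - 1 - 0.01)
        lo = np.floor(ltrb).astype(np.int64)
        hi = lo + 1
        w_hi = (ltrb - lo).astype(np.float32)
        w_lo = 1.0 - w_hi
        logp = F.log_softmax(dist[bi, ai], axis=-1)  # (P, 4, rm)
        pi = np.arange(n_pos)[:, None]
        si = np.arange(4)[None, :]
        nll = -(logp[pi, si, lo] * w_lo + logp[pi, si, hi] * w_hi)
        dfl_loss = (nll.mean(axis=1) * w_pos).sum() * (1.0 / score_sum)

        # ---- segmentation (vectorized per image) --------------------------
        hp, wp = protos.shape[2], protos.shape[3]
        proto_stride = strides[0]
        ys, xs = np.mgrid[0:hp, 0:wp]
        protos_flat = protos.reshape(batch, protos.shape[1], hp * wp)
        seg_loss = None
        for b in range(batch):
            sel = np.nonzero(fg_list[b])[0]
            if len(sel) == 0:
                continue
            g = gidx_list[b][sel]
            gt_masks = np.stack([targets.masks[b][gi] for gi in g]).reshape(len(sel), -1)
            boxes_b = np.stack([targets.boxes[b][gi] for gi in g]) / proto_stride
            inbox = (
                (xs[None] + 0.5 >= boxes_b[:, 0, None, None])
                & (xs[None] + 0.5 <= boxes_b[:, 2, None, None])
                & (ys[None] + 0.5 >= boxes_b[:, 1, None, None])
                & (ys[None] + 0.5 <= boxes_b[:, 3, None, None])
            ).reshape(len(sel), -1).astype(np.float32)
            area = np.clip(inbox.sum(axis=1), 1.0, None)
            logits = F.matmul(coefs[b][sel], protos_flat[b])  # (P_b, hp*wp)
            bce = F.bce_with_logits(logits, gt_masks.astype(np.float32), reduction="none")
            term = ((bce * inbox).sum(axis=1) * (1.0 / area)).sum()
            seg_loss = term if seg_loss is None else seg_loss + term
        seg_loss = seg_loss * (1.0 / n_pos)
    else:
        zero = Tensor(np.zeros(()))
        box_loss = dfl_loss = seg_loss = zero

    total = (
        weights["box"] * box_loss
        + weights["cls"] * cls_loss
        + weights["dfl"] * dfl_loss
        + weights["seg"] * seg_loss
    )
    breakdown = LossBreakdown(
        total=total,
        box=float(box_loss.data),
        cls=float(cls_loss.data),
        dfl=float(dfl_loss.data),
        seg=float(seg_loss.data),
    )
    if not np.isfinite(total.data):
        raise RuntimeError(f"non-finite loss: {breakdown.as_dict()}")
    return breakdown
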
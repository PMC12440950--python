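"""Assembly of the full instance-segmentation network.

Layout: a YOLO-style backbone in which every stage block is a CSP-MUIB
(stem s2; four stages of stride-2 conv + CSP-MUIB; SPPF and a partial
pointwise-spatial-attention block at P5), a neck producing the P3 map
through the PFA fusion unit and the P4 map through the DFS fusion unit
(P5 is a downsample-and-merge path on the DFS output), and an
anchor-free decoupled head emitting class logits, distribution-focal
box offsets and mask coefficients per level plus a stride-8 prototype
map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .blocks import BlockConfig, C2PSA, CSPMUIB, ConvBNAct, SPPF
from .detections import Detection, DetectionList
from .neck import DFS, PFA, PyramidFeatures
from .nn import Conv2d, Module, ModuleList, Sequential, no_grad, profile, seed_init
from .nn import functional as F
from .nn.autograd import Tensor

CHECKPOINT_VERSION = "weednet-ckpt-1"


@dataclass
class ModelConfig:
    """Scalable network configuration.

    ``width_scale``/``depth_scale`` shrink the base channel plan
    ``[64, 128, 256, 512, 1024]`` and the per-stage block repeats, the
    same convention the YOLO family uses for its size variants.
    """

    width_scale: float = 0.5
    depth_scale: float = 0.5
    n_classes: int = 3
    input_size: int = 640
    base_channels: Tuple[int, ...] = (64, 128, 256, 512, 1024)
    base_stage_channels: Tuple[int, ...] = (256, 512, 512, 1024)
    base_stage_depths: Tuple[int, ...] = (4, 2, 2, 2)
    base_depth: int = 2
    neck_base_channels: int = 256
    n_mask_prototypes: int = 32
    reg_max: int = 16
    class_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if min(self.channels(c) for c in self.base_channels) < 8:
            raise ValueError("width_scale shrinks some stage below 8 channels")

    def channels(self, base: int) -> int:
        scaled = int(round(base * self.width_scale / 8)) * 8
        return max(8, scaled)

    def depth(self, base: Optional[int] = None) -> int:
        return max(1, int(round((base or self.base_depth) * self.depth_scale)))

    def to_dict(self) -> dict:
        d = {
            "width_scale": self.width_scale,
            "depth_scale": self.depth_scale,
            "n_classes": self.n_classes,
            "input_size": self.input_size,
            "n_mask_prototypes": self.n_mask_prototypes,
            "reg_max": self.reg_max,
        }
        if self.class_names:
            d["class_names"] = list(self.class_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        if "class_names" in d:
            d = dict(d)
            d["class_names"] = tuple(d["class_names"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ModelSummary:
    n_parameters: int
    flops: int  # 2 x multiply-accumulates at input_size
    input_size: int
    per_module: Dict[str, int] = field(default_factory=dict)

    @property
    def parameters_m(self) -> float:
        return self.n_parameters / 1e6

    @property
    def gflops(self) -> float:
        return self.flops / 1e9


class Backbone(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c = cfg.channels
        n1, n2, n3, n4 = (cfg.depth(d) for d in cfg.base_stage_depths)
        s1, s2, s3, s4 = (c(b) for b in cfg.base_stage_channels)
        self.stem = ConvBNAct(3, c(64), 3, stride=2)
        self.down1 = ConvBNAct(c(64), c(128), 3, stride=2)
        self.stage1 = CSPMUIB(BlockConfig(c(128), s1, n_resuib=n1))
        self.down2 = ConvBNAct(s1, s1, 3, stride=2)
        self.stage2 = CSPMUIB(BlockConfig(s1, s2, n_resuib=n2))
        self.down3 = ConvBNAct(s2, s3, 3, stride=2)
        self.stage3 = CSPMUIB(BlockConfig(s3, s3, n_resuib=n3))
        self.down4 = ConvBNAct(s3, s4, 3, stride=2)
        self.stage4 = CSPMUIB(BlockConfig(s4, s4, n_resuib=n4))
        self.sppf = SPPF(s4, s4)
        self.psa = C2PSA(s4, s4, n=cfg.depth())
        self.out_channels = (s1, s2, s3, s4)

    def forward(self, x: Tensor) -> PyramidFeatures:
        x = self.down1(self.stem(x))
        f2 = self.stage1(x)
        f3 = self.stage2(self.down2(f2))
        f4 = self.stage3(self.down3(f3))
        f5 = self.psa(self.sppf(self.stage4(self.down4(f4))))
        return PyramidFeatures(f2, f3, f4, f5)


class Neck(Module):
    def __init__(self, cfg: ModelConfig, backbone_channels: Tuple[int, int, int, int]):
        super().__init__()
        c2, c3, c4, c5 = backbone_channels
        cn = cfg.channels(cfg.neck_base_channels)
        self.pfa = PFA((c2, c3, c4, c5), cn)
        self.dfs = DFS((c3, c4, c5), cn)
        self.p5_down = ConvBNAct(self.dfs.out_channels, self.dfs.out_channels, 3, stride=2)
        self.p5_merge = CSPMUIB(
            BlockConfig(self.dfs.out_channels + c5, c5, n_resuib=cfg.depth())
        )
        self.out_channels = (cn, self.dfs.out_channels, c5)

    def forward(self, pyramid: PyramidFeatures):
        p3 = self.pfa(pyramid)
        p4 = self.dfs(pyramid)
        p5 = self.p5_merge(F.concat([self.p5_down(p4), pyramid.f5], axis=1))
        return p3, p4, p5


class _Proto(Module):
    """Prototype-mask head at stride 8."""

    def __init__(self, cin: int, hidden: int, n_protos: int):
        super().__init__()
        self.net = Sequential(
            ConvBNAct(cin, hidden, 3),
            ConvBNAct(hidden, hidden, 3),
            Conv2d(hidden, n_protos, 1),
        )

    def forward(self, x):
        return self.net(x)


class Head(Module):
    """Decoupled anchor-free head with depthwise-separable class branch."""

    def __init__(self, cfg: ModelConfig, in_channels: Tuple[int, int, int]):
        super().__init__()
        nc, nm, rm = cfg.n_classes, cfg.n_mask_prototypes, cfg.reg_max
        proto_hidden = cfg.channels(256)
        cb = max(16, in_channels[0] // 4, rm * 4)
        cc = max(in_channels[0], min(nc, 100))
        cm = max(in_channels[0] // 4, nm)
        self.box_branches = ModuleList(
            Sequential(ConvBNAct(c, cb, 3), ConvBNAct(cb, cb, 3), Conv2d(cb, 4 * rm, 1))
            for c in in_channels
        )
        self.cls_branches = ModuleList(
            Sequential(
                ConvBNAct(c, c, 3, groups=c),
                ConvBNAct(c, cc, 1),
                ConvBNAct(cc, cc, 3, groups=cc),
                ConvBNAct(cc, cc, 1),
                Conv2d(cc, nc, 1),
            )
            for c in in_channels
        )
        self.mask_branches = ModuleList(
            Sequential(ConvBNAct(c, cm, 3), ConvBNAct(cm, cm, 3), Conv2d(cm, nm, 1))
            for c in in_channels
        )
        self.proto = _Proto(in_channels[0], proto_hidden, nm)
        # focal-style prior: rare-positive bias on class logits
        for br in self.cls_branches:
            br[-1].bias.data[:] = -np.log(99.0)

    def forward(self, feats):
        outs = []
        for f, bb, cb, mb in zip(feats, self.box_branches, self.cls_branches, self.mask_branches):
            outs.append({"box": bb(f), "cls": cb(f), "mcoef": mb(f)})
        protos = self.proto(feats[0])
        return outs, protos


class SegmentationModel(Module):
    """Backbone + fusion neck + segmentation head."""

    strides = (8, 16, 32)

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(cfg)
        self.neck = Neck(cfg, self.backbone.out_channels)
        self.head = Head(cfg, self.neck.out_channels)

    def forward(self, x: Tensor):
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input height/width must be divisible by 32")
        with profile.tag("backbone"):
            pyramid = self.backbone(x)
        with profile.tag("neck"):
            feats = self.neck(pyramid)
        with profile.tag("head"):
            return self.head(feats)


def build_model(cfg: Optional[ModelConfig] = None, seed: int = 0) -> SegmentationModel:
    """Construct the network with deterministic weight initialization."""
    cfg = cfg or ModelConfig()
    seed_init(seed)
    return SegmentationModel(cfg)


def summarize(model: SegmentationModel, input_size: Optional[int] = None) -> ModelSummary:
    """Parameter count and a profiled FLOP estimate (2 x MACs) at `input_size`."""
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, size, size), np.float32))
    with no_grad(), profile.count_macs() as counted:
        model(x)
    if was_training:
        model.train()
    return ModelSummary(
        n_parameters=model.n_parameters(),
        flops=2 * counted["macs"],
        input_size=size,
        per_module={k: 2 * v for k, v in counted["by_module"].items()},
    )


# ---------------------------------------------------------------------------
# decoding & postprocessing
# ---------------------------------------------------------------------------

def anchor_points(h: int, w: int, stride: int) -> np.ndarray:
    """Grid-cell centers in image pixels, shape (h*w, 2)."""
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return (np.stack([xs, ys], axis=-1).reshape(-1, 2) + 0.5) * stride


def decode_boxes(box_logits: np.ndarray, anchors: np.ndarray, stride: int, reg_max: int) -> np.ndarray:
    """Integrate per-side offset distributions into (x1,y1,x2,y2) boxes.

    `box_logits`: (N, 4*reg_max) raw scores; the expected bin index of
    each softmaxed distribution is the offset in stride units.
    """
    n = box_logits.shape[0]
    z = box_logits.reshape(n, 4, reg_max)
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    dist = (p * np.arange(reg_max)).sum(axis=-1) * stride  # (N,4): l,t,r,b
    x1y1 = anchors - dist[:, :2]
    x2y2 = anchors + dist[:, 2:]
    return np.concatenate([x1y1, x2y2], axis=1)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (N,4)/(M,4) box arrays."""
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> List[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep: List[int] = []
    suppressed = np.zeros(len(boxes), bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        ious = box_iou_matrix(boxes[i : i + 1], boxes)[0]
        suppressed |= ious > iou_threshold
        suppressed[i] = True
    return keep


def postprocess(
    raw_outputs,
    protos,
    image_size: Tuple[int, int],
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.7,
    image_ids: Optional[Sequence[int]] = None,
    max_detections: int = 300,
    reg_max: int = 16,
    strides: Tuple[int, ...] = (8, 16, 32),
) -> List[DetectionList]:
    """Decode raw head outputs into per-image detection lists.

    Boxes come from integrated offset distributions; instance masks are
    sigmoid(coefficients · prototypes) upsampled to the image grid,
    cropped to the box and thresholded at 0.5. Detections are returned
    sorted by descending confidence.
    """
    if not 0.0 <= conf_threshold <= 1.0 or not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    batch = raw_outputs[0]["cls"].shape[0]
    img_h, img_w = image_size
    proto_data = protos.data if isinstance(protos, Tensor) else protos
    results: List[DetectionList] = []
    for b in range(batch):
        boxes_all, scores_all, classes_all, coefs_all = [], [], [], []
        for lvl, stride in enumerate(strides):
            out = raw_outputs[lvl]
            cls = out["cls"].data[b]
            nc, h, w = cls.shape
            scores = 1.0 / (1.0 + np.exp(-cls.reshape(nc, -1).T))  # (hw, nc)
            conf = scores.max(axis=1)
            cls_id = scores.argmax(axis=1)
            sel = conf >= conf_threshold if conf_threshold > 0 else conf > -1
            if conf_threshold >= 1.0:
                sel = conf >= 1.0 + 1e-9  # probability strictly below 1
            if not sel.any():
                continue
            anchors = anchor_points(h, w, stride)[sel]
            box_logits = out["box"].data[b].reshape(4 * reg_max, -1).T[sel]
            boxes = decode_boxes(box_logits, anchors, stride, reg_max)
            coefs = out["mcoef"].data[b].reshape(-1, h * w).T[sel]
            boxes_all.append(boxes)
            scores_all.append(conf[sel])
            classes_all.append(cls_id[sel])
            coefs_all.append(coefs)
        det = DetectionList()
        if boxes_all:
            boxes = np.concatenate(boxes_all)
            scores = np.concatenate(scores_all)
            classes = np.concatenate(classes_all)
            coefs = np.concatenate(coefs_all)
            keep: List[int] = []
            for c in np.unique(classes):
                idx = np.where(classes == c)[0]
                kept = nms(boxes[idx], scores[idx], iou_threshold)
                keep.extend(idx[kept])
            keep = sorted(keep, key=lambda i: -scores[i])[:max_detections]
            pm = proto_data[b]  # (nm, hp, wp)
            image_id = image_ids[b] if image_ids is not None else b
            for i in keep:
                x1, y1, x2, y2 = np.clip(
                    boxes[i], [0, 0, 0, 0], [img_w, img_h, img_w, img_h]
                )
                mask_small = coefs[i] @ pm.reshape(pm.shape[0], -1)
                mask_small = 1.0 / (1.0 + np.exp(-mask_small.reshape(pm.shape[1], pm.shape[2])))
                mask = _upsample_mask(mask_small, (img_h, img_w))
                full = np.zeros((img_h, img_w), bool)
                xi1, yi1 = int(np.floor(x1)), int(np.floor(y1))
                xi2, yi2 = int(np.ceil(x2)), int(np.ceil(y2))
                full[yi1:yi2, xi1:xi2] = mask[yi1:yi2, xi1:xi2] > 0.5
                det.append(
                    Detection(
                        image_id=image_id,
                        class_id=int(classes[i]),
                        confidence=float(scores[i]),
                        box=boxes[i].astype(np.float64),
                        mask=full,
                    )
                )
        results.append(det.sorted_by_confidence())
    return results


def _upsample_mask(mask: np.ndarray, size: Tuple[int, int]) -> np.ndarray:
    t = Tensor(mask[None, None].astype(np.float32))
    with no_grad():
        return F.interpolate_bilinear(t, size).data[0, 0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SegmentationModel, extra: Optional[dict] = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{k: v for k, v in state.items()},
    )


def load_checkpoint(path) -> Tuple[SegmentationModel, dict]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {meta.get('version')!r}")
    model = build_model(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta.get("extra", {})
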
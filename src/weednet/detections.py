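"""Scored predictions: class, confidence, box, binary mask."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np


@dataclass
class Detection:
    image_id: int
    class_id: int
    confidence: float
    box: np.ndarray  # (x1, y1, x2, y2), 0-based half-open pixel coords
    mask: Optional[np.ndarray] = None  # bool (H, W) at image resolution

    def box_area(self) -> float:
        x1, y1, x2, y2 = self.box
        return max(0.0, x2 - x1) * max(0.0, y2 - y1)


@dataclass
class DetectionList:
    detections: List[Detection] = field(default_factory=list)

    def __iter__(self):
        return iter(self.detections)

    def __len__(self):
        return len(self.detections)

    def append(self, d: Detection):
        self.detections.append(d)

    def extend(self, other):
        self.detections.extend(other)

    def sorted_by_confidence(self) -> "DetectionList":
        return DetectionList(sorted(self.detections, key=lambda d: -d.confidence))

    def for_image(self, image_id: int) -> "DetectionList":
        return DetectionList([d for d in self.detections if d.image_id == image_id])
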
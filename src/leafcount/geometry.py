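"""Axis-aligned boxes and detections.

Coordinates are 0-based, half-open: a box occupies the pixel set
``[x_min, x_max) x [y_min, y_max)``, so ``width = x_max - x_min`` with no
off-by-one. Pascal-VOC's 1-based inclusive convention is converted at the
I/O boundary (see :mod:`leafcount.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

ADULT = "adult"
NYMPH = "nymph"
CLASSES = (ADULT, NYMPH)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"negative coordinates in {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def intersection_area(self, other: "BBox") -> float:
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih

    def iou(self, other: "BBox") -> float:
        inter = self.intersection_area(other)
        if inter == 0.0:
            return 0.0
        return inter / (self.area + other.area - inter)

    def clip(self, width: float, height: float) -> "BBox":
        """Clip to an image extent; raises if nothing remains."""
        return BBox(
            min(max(self.x_min, 0.0), width),
            min(max(self.y_min, 0.0), height),
            min(max(self.x_max, 0.0), width),
            min(max(self.y_max, 0.0), height),
        )


@dataclass(frozen=True)
class Detection:
    """A detected (or ground-truth) target: box + class label + confidence."""

    box: BBox
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def translate(self, dx: float, dy: float) -> "Detection":
        return replace(self, box=self.box.translate(dx, dy))


def box_iou(a: BBox, b: BBox) -> float:
    return a.iou(b)
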
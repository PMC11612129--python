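"""Pixel-space geometry shared by the generator and the ROI pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeometryError


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detection region, 0-based half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise GeometryError(f"degenerate box {self}")
        if not 0.0 <= self.confidence <= 1.0:
            raise GeometryError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def clipped(self, image_width: int, image_height: int) -> "BoundingBox":
        return BoundingBox(
            x0=max(0, self.x0), y0=max(0, self.y0),
            x1=min(image_width, self.x1), y1=min(image_height, self.y1),
            confidence=self.confidence,
        )

    def iou(self, other: "BoundingBox") -> float:
        ix0, iy0 = max(self.x0, other.x0), max(self.y0, other.y0)
        ix1, iy1 = min(self.x1, other.x1), min(self.y1, other.y1)
        inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)
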
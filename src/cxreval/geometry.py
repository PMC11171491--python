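"""Pixel-grid bounding-box arithmetic.

Boxes live on an integer pixel grid with the origin at the top-left of the
image and a half-open convention: a box ``(x_min, y_min, x_max, y_max)``
covers the pixels ``[x_min, x_max) x [y_min, y_max)``.  Under this
convention "at least one pixel of overlap" is a discrete, exactly testable
predicate, and boxes that merely share an edge or a corner do *not*
overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "PathologyLabel",
    "PixelBox",
    "intersection_area",
    "union_area",
    "jaccard",
    "overlaps",
    "average_boxes",
]


class PathologyLabel(str, Enum):
    """The six thoracic pathology classes handled by the pipeline."""

    CONSOLIDATION = "consolidation"
    PLEURAL_EFFUSION = "pleural_effusion"
    PNEUMOTHORAX = "pneumothorax"
    ACUTE_PULMONARY_EDEMA = "acute_pulmonary_edema"
    CARDIOMEGALY = "cardiomegaly"
    PULMONARY_NODULE = "pulmonary_nodule"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class PixelBox:
    """Axis-aligned box on the integer pixel grid, half-open on both axes.

    Invariants: ``0 <= x_min < x_max`` and ``0 <= y_min < y_max``, hence
    ``area >= 1``.  Violations raise :class:`ValueError` at construction.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        for name in ("x_min", "y_min", "x_max", "y_max"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.x_min >= self.x_max:
            raise ValueError(
                f"degenerate box: x_min={self.x_min} >= x_max={self.x_max}"
            )
        if self.y_min >= self.y_max:
            raise ValueError(
                f"degenerate box: y_min={self.y_min} >= y_max={self.y_max}"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        """Number of grid pixels covered; always >= 1."""
        return self.width * self.height

    def corners(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def intersection_area(a: PixelBox, b: PixelBox) -> int:
    """Number of grid pixels covered by both boxes.

    Symmetric; zero when the boxes are disjoint, including edge- or
    corner-touching boxes under the half-open convention.
    """
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0 or h <= 0:
        return 0
    return w * h


def union_area(a: PixelBox, b: PixelBox) -> int:
    """Number of grid pixels covered by at least one of the boxes."""
    return a.area + b.area - intersection_area(a, b)


def jaccard(a: PixelBox, b: PixelBox) -> float:
    """Jaccard index (IoU): intersection area over union area.

    1.0 iff the boxes are identical, 0.0 iff they are disjoint.
    """
    inter = intersection_area(a, b)
    if inter == 0:
        return 0.0
    return inter / union_area(a, b)


def overlaps(a: PixelBox, b: PixelBox) -> bool:
    """True iff the boxes share at least one grid pixel."""
    return intersection_area(a, b) >= 1


def _round_half_up(x: float) -> int:
    # round() uses banker's rounding; consensus averaging wants half-up.
    return math.floor(x + 0.5)


def average_boxes(boxes: Sequence[PixelBox] | Iterable[PixelBox]) -> PixelBox:
    """Coordinate-wise mean box, rounded half-up to the pixel grid.

    Used to form a consensus box from several annotators' boxes.  The mean
    preserves the ordering of min/max coordinates, so the result is always
    a valid box.
    """
    boxes = list(boxes)
    if not boxes:
        raise ValueError("average_boxes requires at least one box")
    n = len(boxes)
    return PixelBox(
        _round_half_up(sum(b.x_min for b in boxes) / n),
        _round_half_up(sum(b.y_min for b in boxes) / n),
        _round_half_up(sum(b.x_max for b in boxes) / n),
        _round_half_up(sum(b.y_max for b in boxes) / n),
    )
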
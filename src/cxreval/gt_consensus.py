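"""Consensus ground truth from several annotators' boxes.

Three radiologists (by default) independently draw minimal bounding boxes
around each radiological sign.  A sign enters the reference standard when
a majority of annotators (2 of 3) drew overlapping boxes of the same
pathology — overlap meaning at least one shared pixel.  The consensus box
is the coordinate-wise average of the agreeing annotators' boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .ensemble import _connected_components
from .geometry import (
    PathologyLabel,
    PixelBox,
    average_boxes,
    intersection_area,
    overlaps,
)

__all__ = ["Annotation", "GroundTruthFinding", "consensus_findings", "image_positive"]


@dataclass(frozen=True)
class Annotation:
    """One annotator's box for one radiological sign."""

    box: PixelBox
    label: PathologyLabel
    annotator_id: int

    def __post_init__(self) -> None:
        if not isinstance(self.label, PathologyLabel):
            object.__setattr__(self, "label", PathologyLabel(self.label))
        if self.annotator_id < 1:
            raise ValueError(f"annotator_id must be >= 1, got {self.annotator_id}")


@dataclass(frozen=True)
class GroundTruthFinding:
    """A consensus finding: averaged box, label, and annotator support."""

    box: PixelBox
    label: PathologyLabel
    support: int

    def __post_init__(self) -> None:
        if not isinstance(self.label, PathologyLabel):
            object.__setattr__(self, "label", PathologyLabel(self.label))
        if self.support < 1:
            raise ValueError(f"support must be >= 1, got {self.support}")


def _representative(boxes: list[PixelBox], others: list[PixelBox]) -> PixelBox:
    """Pick one box per annotator inside a component.

    When an annotator contributed several boxes to the same component, the
    one with the largest total overlap with the other annotators' boxes
    represents them; ties break toward the lexicographically smallest
    corner tuple.
    """
    return min(
        boxes,
        key=lambda b: (-sum(intersection_area(b, o) for o in others), b.corners()),
    )


def consensus_findings(
    annotations: Iterable[Annotation], n_annotators: int = 3
) -> list[GroundTruthFinding]:
    """Build the reference standard for one image.

    Per label, connected components of the pairwise-overlap graph are
    formed over all annotators' boxes.  A component whose members come
    from at least ``ceil((n_annotators + 1) / 2)`` distinct annotators
    yields one finding: its box averages one box per agreeing annotator,
    its support is the distinct-annotator count.  Components short of a
    majority are discarded, so an image with no surviving finding of a
    label is a ground-truth negative for that label.
    """
    if n_annotators < 2:
        raise ValueError("consensus requires at least two annotators")
    annotations = list(annotations)
    for a in annotations:
        if not 1 <= a.annotator_id <= n_annotators:
            raise ValueError(
                f"annotator_id {a.annotator_id} outside 1..{n_annotators}"
            )
    majority = n_annotators // 2 + 1

    findings: list[GroundTruthFinding] = []
    for label in PathologyLabel:
        # sort for order-independence of the union-find component order
        boxes = sorted(
            (a for a in annotations if a.label is label),
            key=lambda a: (a.annotator_id, a.box.corners()),
        )
        if not boxes:
            continue
        components = _connected_components(
            boxes, lambda a, b: overlaps(a.box, b.box)
        )
        for component in components:
            by_annotator: dict[int, list[PixelBox]] = {}
            for a in component:
                by_annotator.setdefault(a.annotator_id, []).append(a.box)
            if len(by_annotator) < majority:
                continue
            reps = []
            for aid in sorted(by_annotator):
                own = by_annotator[aid]
                others = [
                    a.box for a in component if a.annotator_id != aid
                ]
                reps.append(_representative(own, others))
            findings.append(
                GroundTruthFinding(
                    box=average_boxes(reps),
                    label=label,
                    support=len(by_annotator),
                )
            )
    findings.sort(key=lambda f: (list(PathologyLabel).index(f.label), f.box.corners()))
    return findings


def image_positive(
    findings: Sequence[GroundTruthFinding], label: PathologyLabel
) -> bool:
    """True iff at least one consensus finding carries ``label``."""
    label = PathologyLabel(label)
    return any(f.label is label for f in findings)
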
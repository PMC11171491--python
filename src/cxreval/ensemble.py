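"""Majority-vote ensembling of several bounding-box detectors.

A committee of ``M`` object-detection models (five by default) each emits
scored, labelled boxes for an image.  Boxes of the same pathology are
grouped into connected components of the pairwise-overlap graph; a
component is retained only when its members come from at least
``min_support`` distinct models (3-of-5 by default), and the retained
component is represented by its single highest-scoring box.  A final
per-pathology score threshold, calibrated on validation data, filters the
emitted boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .geometry import PathologyLabel, PixelBox, overlaps

__all__ = [
    "Detection",
    "ThresholdTable",
    "support_components",
    "vote",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class Detection:
    """A single scored box emitted by one detector model."""

    box: PixelBox
    score: float
    label: PathologyLabel
    model_id: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if not isinstance(self.label, PathologyLabel):
            object.__setattr__(self, "label", PathologyLabel(self.label))
        if self.model_id < 1:
            raise ValueError(f"model_id must be >= 1, got {self.model_id}")


@dataclass(frozen=True)
class ThresholdTable:
    """Per-pathology score thresholds applied after the vote."""

    thresholds: Mapping[PathologyLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = {PathologyLabel(k): float(v) for k, v in self.thresholds.items()}
        missing = [lab.value for lab in PathologyLabel if lab not in table]
        if missing:
            raise ValueError(f"thresholds missing for labels: {missing}")
        for lab, thr in table.items():
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"threshold for {lab.value} outside [0, 1]: {thr}")
        object.__setattr__(self, "thresholds", table)

    @classmethod
    def uniform(cls, value: float = 0.0) -> "ThresholdTable":
        return cls({lab: value for lab in PathologyLabel})

    def __getitem__(self, label: PathologyLabel) -> float:
        return self.thresholds[PathologyLabel(label)]


def _connected_components(items: Sequence, adjacent) -> list[list]:
    """Connected components (union-find) over ``items`` under ``adjacent``.

    Components are returned in order of their first member's position in
    the input; members keep input order, so the result is deterministic.
    """
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if adjacent(items[i], items[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i])
    return [groups[r] for r in sorted(groups, key=lambda r: min(
        i for i in range(n) if find(i) == r))]


def support_components(
    detections: Sequence[Detection], label: PathologyLabel
) -> list[list[Detection]]:
    """Connected components of the pairwise-overlap graph for one label.

    All detections must carry ``label`` (the vote is per pathology; boxes
    of different pathologies never support each other).
    """
    label = PathologyLabel(label)
    for d in detections:
        if d.label is not label:
            raise ValueError(
                f"support_components called with mixed labels: expected "
                f"{label.value}, found {d.label.value}"
            )
    return _connected_components(
        list(detections), lambda a, b: overlaps(a.box, b.box)
    )


def _selection_key(d: Detection):
    # highest score wins; ties broken toward the lowest model id, then the
    # lexicographically smallest corner tuple, for determinism
    return (-d.score, d.model_id, d.box.corners())


def vote(
    per_model_detections: Sequence[Sequence[Detection]],
    thresholds: ThresholdTable,
    min_support: int = 3,
) -> list[Detection]:
    """Run the majority vote over the detections of ``M`` models.

    Per pathology, connected overlap components are built over the union
    of all models' boxes; a component survives when its members come from
    at least ``min_support`` distinct models, and contributes its single
    highest-scoring box to the output.  Emitted boxes scoring below the
    pathology's threshold are dropped as a last step (sub-threshold boxes
    still vote).  Output is ordered by label enumeration order, then by
    descending score.
    """
    n_models = len(per_model_detections)
    if min_support > n_models:
        raise ValueError(
            f"min_support={min_support} exceeds the number of models {n_models}"
        )
    pooled: list[Detection] = []
    for i, dets in enumerate(per_model_detections, start=1):
        for d in dets:
            if not 1 <= d.model_id <= n_models:
                raise ValueError(
                    f"model_id {d.model_id} outside 1..{n_models}"
                )
            if d.model_id != i:
                raise ValueError(
                    f"detection with model_id {d.model_id} found in list {i}"
                )
            pooled.append(d)

    out: list[Detection] = []
    for label in PathologyLabel:
        candidates = [d for d in pooled if d.label is label]
        if not candidates:
            continue
        emitted: list[Detection] = []
        for component in support_components(candidates, label):
            support = len({d.model_id for d in component})
            if support < min_support:
                continue
            emitted.append(min(component, key=_selection_key))
        emitted = [d for d in emitted if d.score >= thresholds[label]]
        out.extend(sorted(emitted, key=_selection_key))
    return out


def calibrate_thresholds(
    validation_scores: Mapping[PathologyLabel, Iterable[tuple[float, bool]]],
) -> ThresholdTable:
    """Choose one score threshold per pathology on validation data.

    Candidate cut-points are the midpoints between adjacent distinct
    sorted scores; the cut maximising Youden's J (sensitivity +
    specificity - 1, with a box counted positive when its score is >= the
    cut) is returned, ties broken toward the higher threshold.
    """
    table: dict[PathologyLabel, float] = {}
    for label in PathologyLabel:
        if label not in validation_scores:
            raise ValueError(f"no validation scores for {label.value}")
        pairs = [(float(s), bool(y)) for s, y in validation_scores[label]]
        pos = [s for s, y in pairs if y]
        neg = [s for s, y in pairs if not y]
        if not pos or not neg:
            raise ValueError(
                f"calibration for {label.value} needs at least one positive "
                f"and one negative score"
            )
        distinct = sorted(set(pos) | set(neg))
        cuts = [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
        if not cuts:  # all scores identical; only the trivial cut exists
            cuts = [distinct[0]]
        best_thr, best_j = None, None
        for thr in cuts:
            sens = sum(s >= thr for s in pos) / len(pos)
            spec = sum(s < thr for s in neg) / len(neg)
            j = sens + spec - 1.0
            if best_j is None or j > best_j or (j == best_j and thr > best_thr):
                best_thr, best_j = thr, j
        table[label] = best_thr
    return ThresholdTable(table)
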
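"""Standalone performance evaluation against consensus ground truth.

Each image is classified per pathology into TP / FP / TN / FN at the
image level: a ground-truth-positive image is a TP when any predicted box
overlaps any consensus box (one shared pixel suffices) and an FN
otherwise; a ground-truth-negative image is an FP when any predicted box
of that pathology is present and a TN otherwise.  From the tallied
confusion counts the usual panel (sensitivity, specificity, PPV, NPV,
FPR, FNR) is derived, with Wilson score intervals for proportions,
rank-statistic ROC AUC for scored outputs, and stratified bootstrap
percentile intervals for the AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .ensemble import Detection
from .geometry import PathologyLabel, overlaps
from .gt_consensus import GroundTruthFinding, image_positive

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "classify_image",
    "confusion_counts",
    "metric_panel",
    "wilson_ci",
    "roc_auc",
    "bootstrap_auc_ci",
    "macro_average",
]


@dataclass
class ConfusionCounts:
    """Image-level confusion counts for one pathology."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def positives(self) -> int:
        """Ground-truth-positive images for the label."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Ground-truth-negative images for the label."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.positives + self.negatives

    def add(self, outcome: str) -> None:
        if outcome not in ("TP", "FN", "FP", "TN"):
            raise ValueError(f"unknown outcome {outcome!r}")
        name = outcome.lower()
        setattr(self, name, getattr(self, name) + 1)


@dataclass
class MetricSet:
    """Derived metric panel; undefined metrics are ``None``, never coerced.

    ``ci`` maps a metric name to its 95% Wilson interval when computed;
    ``auc`` and ``auc_ci`` are attached only when per-image scores exist.
    """

    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    fpr: float | None = None
    fnr: float | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def classify_image(
    predictions: Sequence[Detection],
    findings: Sequence[GroundTruthFinding],
    label: PathologyLabel,
) -> str:
    """Classify one image for one pathology into TP, FN, FP, or TN.

    Ground-truth-positive images are TP when any prediction of the label
    overlaps any consensus finding of the label, else FN (a positive image
    with only stray boxes is a miss, not a false alarm).  Ground-truth
    negatives are FP when any prediction of the label is present, else TN.
    """
    label = PathologyLabel(label)
    preds = [p for p in predictions if p.label is label]
    gts = [f for f in findings if f.label is label]
    if image_positive(gts, label):
        hit = any(overlaps(p.box, g.box) for p in preds for g in gts)
        return "TP" if hit else "FN"
    return "FP" if preds else "TN"


def confusion_counts(
    images: Iterable[tuple[Sequence[Detection], Sequence[GroundTruthFinding]]],
    labels: Sequence[PathologyLabel] = tuple(PathologyLabel),
) -> dict[PathologyLabel, ConfusionCounts]:
    """Tally :func:`classify_image` over a dataset, per pathology.

    ``images`` yields ``(predictions, findings)`` pairs, one per image.
    """
    counts = {PathologyLabel(lab): ConfusionCounts() for lab in labels}
    for predictions, findings in images:
        for label, c in counts.items():
            c.add(classify_image(predictions, findings, label))
    return counts


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("wilson_ci requires n >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside 0..{n}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # boundary cases are exact in the closed form; undo float round-off
    if successes == n:
        hi = 1.0
    if successes == 0:
        lo = 0.0
    return float(lo), float(hi)


def metric_panel(c: ConfusionCounts, ci: bool = False, level: float = 0.95) -> MetricSet:
    """Derive the metric panel from confusion counts.

    A metric with a zero denominator is reported as undefined (``None``)
    with a warning rather than coerced to 0 or 1.
    """
    m = MetricSet()

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            warnings.warn(
                f"{name} undefined: zero denominator", stacklevel=3
            )
            return None
        return num / den

    m.sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    m.fnr = None if m.sensitivity is None else c.fn / (c.fn + c.tp)
    m.specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    m.fpr = None if m.specificity is None else c.fp / (c.fp + c.tn)
    m.ppv = ratio(c.tp, c.tp + c.fp, "ppv")
    m.npv = ratio(c.tn, c.tn + c.fn, "npv")
    if ci:
        for name, (k, n) in {
            "sensitivity": (c.tp, c.tp + c.fn),
            "specificity": (c.tn, c.tn + c.fp),
            "ppv": (c.tp, c.tp + c.fp),
            "npv": (c.tn, c.tn + c.fn),
        }.items():
            if n > 0:
                m.ci[name] = wilson_ci(k, n, level)
    return m


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC requires at least one positive and one negative")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-statistic AUC: P(random positive outscores a random negative),
    ties counted one half; equals the trapezoidal area under the empirical
    ROC curve."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    return float(roc_auc_score(y, s))


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the AUC.

    Images are resampled with replacement within each class (stratified),
    so every resample retains both classes; deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _check_two_classes(y)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos, neg = s[y], s[~y]
    aucs = np.empty(B)
    for b in range(B):
        rp = rng.choice(pos, size=pos.size, replace=True)
        rn = rng.choice(neg, size=neg.size, replace=True)
        resampled = np.concatenate([rp, rn])
        truth = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        aucs[b] = roc_auc_score(truth, resampled)
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def macro_average(per_label_values: Mapping[PathologyLabel, float]) -> float:
    """Unweighted mean of a per-pathology metric over all six classes."""
    values = {PathologyLabel(k): v for k, v in per_label_values.items()}
    missing = [lab.value for lab in PathologyLabel if lab not in values]
    if missing:
        raise ValueError(f"macro_average missing labels: {missing}")
    return float(np.mean([values[lab] for lab in PathologyLabel]))
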
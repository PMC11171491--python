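"""End-to-end orchestration: vote, consensus, evaluation, MRMC report.

These helpers bind the per-image operations into study-level runs and
produce the tabular reports (per-anomaly confusion counts, the metric
panel, and the aided-vs-unaided summary).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .ensemble import Detection, ThresholdTable, vote
from .evaluation import (
    ConfusionCounts,
    MetricSet,
    bootstrap_auc_ci,
    confusion_counts,
    metric_panel,
    roc_auc,
)
from .geometry import PathologyLabel
from .gt_consensus import Annotation, GroundTruthFinding, consensus_findings
from .synthetic import SimulatedStudy

__all__ = [
    "ensemble_study",
    "consensus_study",
    "evaluate_study",
    "counts_table",
    "metrics_table",
    "standalone_report",
]


def _per_model_lists(
    detections: Sequence[Detection], n_models: int
) -> list[list[Detection]]:
    lists: list[list[Detection]] = [[] for _ in range(n_models)]
    for d in detections:
        if not 1 <= d.model_id <= n_models:
            raise ValueError(f"model_id {d.model_id} outside 1..{n_models}")
        lists[d.model_id - 1].append(d)
    return lists


def ensemble_study(
    detections: Mapping[str, Sequence[Detection]],
    thresholds: ThresholdTable,
    n_models: int = 5,
    min_support: int = 3,
) -> dict[str, list[Detection]]:
    """Run the majority vote image by image."""
    return {
        image_id: vote(_per_model_lists(dets, n_models), thresholds, min_support)
        for image_id, dets in detections.items()
    }


def consensus_study(
    annotations: Mapping[str, Sequence[Annotation]],
    n_annotators: int = 3,
) -> dict[str, list[GroundTruthFinding]]:
    """Build the consensus reference standard image by image."""
    return {
        image_id: consensus_findings(anns, n_annotators)
        for image_id, anns in annotations.items()
    }


def evaluate_study(
    predictions: Mapping[str, Sequence[Detection]],
    findings: Mapping[str, Sequence[GroundTruthFinding]],
    evaluation_sets: Mapping[PathologyLabel, Sequence[str]],
    with_auc: bool = True,
    bootstrap: int = 0,
    seed: int | None = None,
) -> tuple[dict[PathologyLabel, ConfusionCounts], dict[PathologyLabel, MetricSet]]:
    """Per-pathology confusion counts and metric panel for a study.

    ``evaluation_sets`` names, per pathology, the images scored for that
    pathology (its designed positives plus the shared negatives).  When
    ``with_auc`` is set, an image's score for a pathology is the highest
    voted-detection score of that pathology on the image (0 when none),
    and a stratified percentile bootstrap CI is attached when
    ``bootstrap`` > 0.
    """
    counts: dict[PathologyLabel, ConfusionCounts] = {}
    metrics: dict[PathologyLabel, MetricSet] = {}
    for label, image_ids in evaluation_sets.items():
        label = PathologyLabel(label)
        pairs = [
            (predictions.get(i, ()), findings.get(i, ())) for i in image_ids
        ]
        counts[label] = confusion_counts(pairs, labels=[label])[label]
        m = metric_panel(counts[label], ci=True)
        if with_auc:
            scores, truths = [], []
            for preds, gts in pairs:
                same = [d.score for d in preds if d.label is label]
                scores.append(max(same, default=0.0))
                truths.append(any(f.label is label for f in gts))
            if any(truths) and not all(truths):
                m.auc = roc_auc(scores, truths)
                if bootstrap > 0:
                    m.auc_ci = bootstrap_auc_ci(
                        scores, truths, B=bootstrap, seed=seed
                    )
        metrics[label] = m
    return counts, metrics


def counts_table(counts: Mapping[PathologyLabel, ConfusionCounts]) -> pd.DataFrame:
    """Per-anomaly TP/FN/FP/TN table."""
    rows = []
    for label in PathologyLabel:
        if label not in counts:
            continue
        c = counts[label]
        rows.append(
            {"anomaly": label.value, "tp": c.tp, "fn": c.fn, "fp": c.fp, "tn": c.tn}
        )
    return pd.DataFrame(rows)


def metrics_table(metrics: Mapping[PathologyLabel, MetricSet]) -> pd.DataFrame:
    """Per-anomaly metric panel table."""
    rows = []
    for label in PathologyLabel:
        if label not in metrics:
            continue
        m = metrics[label]
        row = {
            "anomaly": label.value,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "npv": m.npv,
            "ppv": m.ppv,
            "fpr": m.fpr,
            "fnr": m.fnr,
            "auc": m.auc,
        }
        if m.auc_ci is not None:
            row["auc_ci_lo"], row["auc_ci_hi"] = m.auc_ci
        for name, (lo, hi) in m.ci.items():
            row[f"{name}_ci_lo"], row[f"{name}_ci_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def standalone_report(
    study: SimulatedStudy,
    thresholds: ThresholdTable | None = None,
    min_support: int = 3,
    bootstrap: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full standalone evaluation of a simulated study.

    Votes the detector outputs, builds the annotator consensus, and
    evaluates per pathology on the designed evaluation sets; returns the
    confusion-count and metric tables.
    """
    thresholds = thresholds or ThresholdTable.uniform(0.0)
    voted = ensemble_study(
        study.detections,
        thresholds,
        n_models=len(study.config.detectors),
        min_support=min_support,
    )
    findings = consensus_study(
        study.annotations, n_annotators=len(study.config.annotators)
    )
    counts, metrics = evaluate_study(
        voted,
        findings,
        study.evaluation_sets(),
        bootstrap=bootstrap,
        seed=seed,
    )
    return counts_table(counts), metrics_table(metrics)
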
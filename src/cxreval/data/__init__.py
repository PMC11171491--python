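"""Bundled reference inputs.

``reference_study.json`` carries the published inputs of a multicenter
chest-radiograph evaluation: per-anomaly image-level confusion counts
from the standalone phase (500 positive / 1000 negative images per
anomaly), the per-anomaly ROC AUCs, and the nine-reader aided/unaided
outcome means and SDs.  These are *inputs* to the arithmetic in this
package — the metric panel, aggregates, and comparison statistics are
always recomputed from them, never stored.
"""

from __future__ import annotations

import json
from importlib import resources

from ..evaluation import ConfusionCounts
from ..geometry import PathologyLabel

__all__ = ["load_reference_study", "reference_confusion_counts"]


def load_reference_study() -> dict:
    """The raw bundled reference inputs as a dict."""
    with resources.files(__package__).joinpath("reference_study.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def reference_confusion_counts() -> dict[PathologyLabel, ConfusionCounts]:
    """Per-anomaly confusion counts as :class:`ConfusionCounts`."""
    raw = load_reference_study()["confusion_counts"]
    return {
        PathologyLabel(label): ConfusionCounts(**counts)
        for label, counts in raw.items()
    }
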
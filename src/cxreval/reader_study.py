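"""Multi-reader multi-case (MRMC) aided-vs-unaided comparison.

Nine readers (by default) interpret one set of radiographs without AI
assistance and another set with it.  Per reader and condition the
pipeline computes mean reading time, macro-averaged per-anomaly
sensitivity and specificity, and — when per-image confidences are
recorded — a rank-based AUC.  Conditions are compared outcome-by-outcome
with a Welch two-sample t-test, normal-theory 95% confidence half-widths,
and a signed percent change relative to the unaided baseline.

The module also hosts the AUC-based sample-size calculation
(Hanley–McNeil variance) used to plan per-anomaly case counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .evaluation import roc_auc
from .geometry import PathologyLabel

__all__ = [
    "ReaderRecord",
    "ComparisonRow",
    "MRMCSummary",
    "reader_metrics",
    "compare_conditions",
    "percent_change",
    "sample_size_auc",
    "mrmc_summary",
]

CONDITIONS = ("unaided", "aided")


@dataclass(frozen=True)
class ReaderRecord:
    """One reader's call on one image for one pathology."""

    reader_id: int
    condition: str
    image_id: str
    label: PathologyLabel
    call: bool
    confidence: float | None
    time_s: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not isinstance(self.label, PathologyLabel):
            object.__setattr__(self, "label", PathologyLabel(self.label))
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")
        if not self.time_s > 0:
            raise ValueError(f"reading time must be positive, got {self.time_s}")


@dataclass
class ComparisonRow:
    """One outcome's aided-vs-unaided comparison (one row of the summary)."""

    outcome: str
    unaided_mean: float
    unaided_sd: float
    unaided_var: float
    unaided_ci_halfwidth: float
    aided_mean: float
    aided_sd: float
    aided_var: float
    aided_ci_halfwidth: float
    t_statistic: float
    p_value: float
    percent_change: float


@dataclass
class MRMCSummary:
    """Comparison rows keyed by outcome name (time_s, auc, sensitivity, ...)."""

    rows: dict[str, ComparisonRow] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        return [vars(row) for row in self.rows.values()]


def reader_metrics(
    records: Iterable[ReaderRecord],
    truth: Mapping[str, frozenset | set],
) -> tuple[float, float]:
    """Macro-averaged (sensitivity, specificity) for one reader-condition.

    ``truth`` maps image id to the set of ground-truth-positive labels for
    that image.  Per anomaly, sensitivity is the proportion of
    ground-truth-positive images the reader flagged and specificity the
    proportion of negative images left clean; the per-anomaly values are
    then macro-averaged.  A label with no positive (or no negative) image
    is excluded from the corresponding average with a warning.
    """
    records = list(records)
    sens_parts: list[float] = []
    spec_parts: list[float] = []
    for label in PathologyLabel:
        hits = misses = alarms = cleans = 0
        for r in records:
            if r.label is not label:
                continue
            if r.image_id not in truth:
                raise ValueError(f"no ground truth for image {r.image_id!r}")
            is_pos = label in truth[r.image_id]
            if is_pos:
                hits += r.call
                misses += not r.call
            else:
                alarms += r.call
                cleans += not r.call
        if hits + misses > 0:
            sens_parts.append(hits / (hits + misses))
        else:
            warnings.warn(f"no positive images for {label.value}; excluded")
        if alarms + cleans > 0:
            spec_parts.append(cleans / (alarms + cleans))
        else:
            warnings.warn(f"no negative images for {label.value}; excluded")
    if not sens_parts or not spec_parts:
        raise ValueError("no label had both classes represented")
    return float(np.mean(sens_parts)), float(np.mean(spec_parts))


_Z95 = 1.959964


def compare_conditions(
    unaided: Sequence[float],
    aided: Sequence[float],
    outcome: str = "outcome",
) -> ComparisonRow:
    """Welch two-sided t-test between per-reader outcome values.

    Reports per-condition mean, sample SD, variance, and normal-theory
    95% CI half-width (1.96 * sd / sqrt(n)), plus the percent change of
    the aided mean relative to the unaided mean.
    """
    u = np.asarray(unaided, dtype=float)
    a = np.asarray(aided, dtype=float)
    if u.size < 2 or a.size < 2:
        raise ValueError("need at least two readers per condition")
    t, p = stats.ttest_ind(a, u, equal_var=False)
    if math.isnan(t):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0

    def summary(x: np.ndarray) -> tuple[float, float, float, float]:
        sd = float(np.std(x, ddof=1))
        return float(np.mean(x)), sd, sd**2, _Z95 * sd / math.sqrt(x.size)

    um, usd, uvar, uhw = summary(u)
    am, asd, avar, ahw = summary(a)
    return ComparisonRow(
        outcome=outcome,
        unaided_mean=um,
        unaided_sd=usd,
        unaided_var=uvar,
        unaided_ci_halfwidth=uhw,
        aided_mean=am,
        aided_sd=asd,
        aided_var=avar,
        aided_ci_halfwidth=ahw,
        t_statistic=float(t),
        p_value=float(p),
        percent_change=percent_change(um, am),
    )


def percent_change(baseline: float, treated: float) -> float:
    """Signed percent change of ``treated`` relative to ``baseline``,
    reported to two decimals."""
    if baseline == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return round(100.0 * (treated - baseline) / baseline, 2)


def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil variance of the empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def sample_size_auc(
    alpha: float = 0.05,
    beta: float = 0.20,
    auc_alt: float = 0.80,
    auc_null: float = 0.50,
) -> tuple[int, int]:
    """Smallest equal per-group case counts for a two-sided z-test of the
    AUC against ``auc_null``.

    Uses the Hanley–McNeil variance under the null for the significance
    term and under the alternative for the power term; returns
    ``(n_positive, n_negative)`` with equal groups.
    """
    if not (0.5 <= auc_null < auc_alt < 1.0):
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(1 - beta)
    delta = auc_alt - auc_null
    n = 2
    while True:
        lhs = z_a * math.sqrt(_hanley_mcneil_var(auc_null, n, n)) + z_b * math.sqrt(
            _hanley_mcneil_var(auc_alt, n, n)
        )
        if lhs <= delta:
            return n, n
        n += 1
        if n > 10**6:  # pragma: no cover - guard against pathological inputs
            raise RuntimeError("sample size search did not converge")


def mrmc_summary(
    records: Iterable[ReaderRecord],
    truth: Mapping[str, frozenset | set],
) -> MRMCSummary:
    """Full aided-vs-unaided comparison from raw reader records.

    Per reader and condition: mean reading time per image, macro
    sensitivity/specificity, and rank-based AUC over per-image confidences
    (an image's confidence for a label is the recorded value; AUC is
    skipped with a warning when confidences are absent).
    """
    records = list(records)
    by_rc: dict[tuple[int, str], list[ReaderRecord]] = {}
    for r in records:
        by_rc.setdefault((r.reader_id, r.condition), []).append(r)

    outcomes: dict[str, dict[str, list[float]]] = {
        name: {c: [] for c in CONDITIONS}
        for name in ("time_s", "auc", "sensitivity", "specificity")
    }
    have_conf = all(r.confidence is not None for r in records)
    if not have_conf:
        warnings.warn("confidence missing for some records; reader AUC skipped")

    for (reader, condition), recs in sorted(by_rc.items()):
        per_image_time: dict[str, float] = {}
        for r in recs:
            per_image_time[r.image_id] = r.time_s
        outcomes["time_s"][condition].append(float(np.mean(list(per_image_time.values()))))
        sens, spec = reader_metrics(recs, truth)
        outcomes["sensitivity"][condition].append(sens)
        outcomes["specificity"][condition].append(spec)
        if have_conf:
            scores = [r.confidence for r in recs]
            labels = [r.label in truth[r.image_id] for r in recs]
            outcomes["auc"][condition].append(roc_auc(scores, labels))

    summary = MRMCSummary()
    for name, groups in outcomes.items():
        if not groups["unaided"] or not groups["aided"]:
            continue
        summary.rows[name] = compare_conditions(
            groups["unaided"], groups["aided"], outcome=name
        )
    return summary
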
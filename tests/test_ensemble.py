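from __future__ import annotations

import numpy as np
import pytest

from cxreval.ensemble import (
    Detection,
    ThresholdTable,
    calibrate_thresholds,
    support_components,
    vote,
)
from cxreval.geometry import PathologyLabel, PixelBox

from .oracles import brute_vote, brute_youden_sweep

CONS = PathologyLabel.CONSOLIDATION
EFF = PathologyLabel.PLEURAL_EFFUSION
ZERO = ThresholdTable.uniform(0.0)


def det(x0, y0, x1, y1, score, model, label=CONS):
    return Detection(PixelBox(x0, y0, x1, y1), score, label, model)


class TestSupportComponents:
    def test_empty_input(self):
        assert support_components([], CONS) == []

    def test_disjoint_boxes_are_singletons(self):
        a, b = det(0, 0, 5, 5, 0.5, 1), det(20, 20, 30, 30, 0.5, 2)
        assert support_components([a, b], CONS) == [[a], [b]]

    def test_overlap_chain_is_one_component(self):
        # a overlaps b, b overlaps c, a and c are disjoint
        a = det(0, 0, 10, 10, 0.5, 1)
        b = det(8, 0, 18, 10, 0.5, 2)
        c = det(16, 0, 26, 10, 0.5, 3)
        (comp,) = support_components([a, b, c], CONS)
        assert set(comp) == {a, b, c}

    def test_mixed_labels_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            support_components([det(0, 0, 5, 5, 0.5, 1, EFF)], CONS)


class TestVote:
    def test_all_models_empty(self):
        assert vote([[], [], [], [], []], ZERO) == []

    def test_single_model_box_rejected_at_default_support(self):
        lists = [[det(0, 0, 10, 10, 0.9, 1)], [], [], [], []]
        assert vote(lists, ZERO) == []

    def test_highest_score_box_wins(self):
        lists = [
            [det(0, 0, 10, 10, 0.6, 1)],
            [det(2, 2, 12, 12, 0.7, 2)],
            [det(4, 4, 14, 14, 0.8, 3)],
            [],
            [],
        ]
        assert vote(lists, ZERO) == [det(4, 4, 14, 14, 0.8, 3)]

    def test_no_cross_label_voting(self):
        # same spot, two labels, three models each: one winner per label
        lists = [
            [det(0, 0, 10, 10, 0.5, 1), det(0, 0, 10, 10, 0.6, 1, EFF)],
            [det(1, 1, 11, 11, 0.7, 2), det(1, 1, 11, 11, 0.4, 2, EFF)],
            [det(2, 2, 12, 12, 0.6, 3), det(2, 2, 12, 12, 0.5, 3, EFF)],
            [],
            [],
        ]
        out = vote(lists, ZERO)
        assert {d.label for d in out} == {CONS, EFF}
        assert {d.score for d in out} == {0.7, 0.6}

    def test_threshold_filters_after_voting(self):
        # sub-threshold boxes still vote; only the emitted box is filtered
        thr = ThresholdTable({lab: 0.65 for lab in PathologyLabel})
        lists = [
            [det(0, 0, 10, 10, 0.2, 1)],
            [det(1, 1, 11, 11, 0.3, 2)],
            [det(2, 2, 12, 12, 0.7, 3)],
            [],
            [],
        ]
        assert vote(lists, thr) == [det(2, 2, 12, 12, 0.7, 3)]
        thr_high = ThresholdTable({lab: 0.75 for lab in PathologyLabel})
        assert vote(lists, thr_high) == []

    def test_min_support_one_single_model_is_threshold_filter(self):
        dets = [det(0, 0, 5, 5, 0.3, 1), det(20, 20, 25, 25, 0.8, 1)]
        thr = ThresholdTable({lab: 0.5 for lab in PathologyLabel})
        assert vote([dets], thr, min_support=1) == [det(20, 20, 25, 25, 0.8, 1)]

    def test_support_counts_distinct_models_not_boxes(self):
        # three overlapping boxes from only two models: support 2, rejected
        lists = [
            [det(0, 0, 10, 10, 0.5, 1), det(1, 1, 11, 11, 0.6, 1)],
            [det(2, 2, 12, 12, 0.7, 2)],
            [],
            [],
            [],
        ]
        assert vote(lists, ZERO) == []

    def test_min_support_exceeding_models_rejected(self):
        with pytest.raises(ValueError, match="min_support"):
            vote([[], []], ZERO, min_support=3)

    def test_foreign_model_id_rejected(self):
        with pytest.raises(ValueError):
            vote([[det(0, 0, 5, 5, 0.5, 7)]], ZERO, min_support=1)

    def test_threshold_monotonicity(self, rng):
        lists = _random_instance(rng, n=8)
        prev = None
        for t in np.linspace(0, 1, 6):
            thr = ThresholdTable({lab: float(t) for lab in PathologyLabel})
            n_out = len(vote(lists, thr))
            if prev is not None:
                assert n_out <= prev
            prev = n_out

    def test_output_boxes_come_from_the_input(self, rng):
        for _ in range(20):
            lists = _random_instance(rng, n=8)
            pooled = {d for dets in lists for d in dets}
            assert set(vote(lists, ZERO)) <= pooled

    def test_matches_brute_force_oracle_on_small_instances(self, rng):
        thr = ThresholdTable({lab: 0.3 for lab in PathologyLabel})
        for _ in range(150):
            lists = _random_instance(rng, n=int(rng.integers(0, 9)))
            got = sorted(vote(lists, thr), key=lambda d: d.box.corners())
            want = sorted(brute_vote(lists, thr, 3), key=lambda d: d.box.corners())
            assert got == want


def _random_instance(rng: np.random.Generator, n: int) -> list[list[Detection]]:
    """Up to n detections spread over 5 models, two labels, small grid."""
    lists: list[list[Detection]] = [[] for _ in range(5)]
    for _ in range(n):
        m = int(rng.integers(1, 6))
        x0 = int(rng.integers(0, 12))
        y0 = int(rng.integers(0, 12))
        lists[m - 1].append(
            Detection(
                PixelBox(x0, y0, x0 + int(rng.integers(1, 8)), y0 + int(rng.integers(1, 8))),
                score=round(float(rng.random()), 3),
                label=CONS if rng.random() < 0.7 else EFF,
                model_id=m,
            )
        )
    return lists


class TestCalibrateThresholds:
    @staticmethod
    def _table(pos, neg):
        return {lab: [(s, True) for s in pos] + [(s, False) for s in neg]
                for lab in PathologyLabel}

    def test_perfect_separation_gives_midpoint(self):
        table = calibrate_thresholds(self._table([0.9, 0.9], [0.1, 0.1]))
        for lab in PathologyLabel:
            assert table[lab] == pytest.approx(0.5)

    def test_matches_exhaustive_sweep(self):
        pos, neg = [0.8, 0.6], [0.7, 0.2]
        table = calibrate_thresholds(self._table(pos, neg))
        want_thr, _ = brute_youden_sweep(pos, neg)
        assert table[CONS] == pytest.approx(want_thr)

    def test_random_instances_match_sweep(self, rng):
        for _ in range(50):
            pos = list(np.round(rng.random(int(rng.integers(1, 8))), 2))
            neg = list(np.round(rng.random(int(rng.integers(1, 8))), 2))
            table = calibrate_thresholds(self._table(pos, neg))
            want_thr, want_j = brute_youden_sweep(pos, neg)
            got = table[CONS]
            sens = sum(s >= got for s in pos) / len(pos)
            spec = sum(s < got for s in neg) / len(neg)
            assert sens + spec - 1 == pytest.approx(want_j)
            assert got == pytest.approx(want_thr)

    def test_duplication_leaves_threshold_unchanged(self):
        pos, neg = [0.8, 0.6], [0.7, 0.2]
        once = calibrate_thresholds(self._table(pos, neg))
        twice = calibrate_thresholds(self._table(pos * 2, neg * 2))
        assert once[CONS] == twice[CONS]

    def test_single_class_rejected_naming_the_pathology(self):
        scores = self._table([0.9], [0.1])
        scores[EFF] = [(0.5, True)]
        with pytest.raises(ValueError, match="pleural_effusion"):
            calibrate_thresholds(scores)


def test_vote_suppresses_independent_false_positives():
    """With spatially independent false positives and no shared distractor
    sites, the 3-of-5 vote's image-level false-positive rate sits well
    below every single model's rate."""
    from cxreval.pipeline import consensus_study, ensemble_study, evaluate_study
    from cxreval.synthetic import (
        DetectorProfile,
        SimulationConfig,
        simulate_study,
    )

    config = SimulationConfig(
        n_positive_per_label=0,
        n_negative_per_label=400,
        detectors=tuple(
            DetectorProfile(sensitivity=0.95, fp_rate=0.5) for _ in range(5)
        ),
        shared_fp_rate=0.0,
    )
    study = simulate_study(config, seed=77)
    voted = ensemble_study(study.detections, ZERO, n_models=5)
    # image-level: any false box of any label counts the image as a false call
    voted_rate = np.mean([bool(voted[i.image_id]) for i in study.truth])
    single_rates = []
    for m in range(1, 6):
        rate = np.mean(
            [
                any(d.model_id == m for d in study.detections[i.image_id])
                for i in study.truth
            ]
        )
        single_rates.append(rate)
    # per-model Poisson(0.5) -> ~39% of images carry a false box; the margin
    # here is far outside binomial noise at n=400
    assert min(single_rates) > 0.3
    assert voted_rate < min(single_rates) - 0.2
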
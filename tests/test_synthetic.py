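from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from cxreval.geometry import PathologyLabel
from cxreval.gt_consensus import consensus_findings
from cxreval.synthetic import (
    AnnotatorProfile,
    DetectorProfile,
    ReaderConditionProfile,
    SimulationConfig,
    simulate_annotators,
    simulate_detections,
    simulate_ground_truth,
    simulate_readers,
    simulate_reader_pool,
    simulate_study,
)

CONS = PathologyLabel.CONSOLIDATION


def tiny_config(**kwargs) -> SimulationConfig:
    base = dict(n_positive_per_label=25, n_negative_per_label=50)
    base.update(kwargs)
    return SimulationConfig(**base)


class TestGroundTruth:
    def test_study_composition(self):
        truth = simulate_ground_truth(tiny_config(), seed=0)
        for label in PathologyLabel:
            positives = [t for t in truth if label in t.positive_labels]
            assert len(positives) == 25
        negatives = [t for t in truth if not t.lesions]
        assert len(negatives) == 50

    def test_boxes_lie_within_image_bounds(self):
        truth = simulate_ground_truth(tiny_config(), seed=1)
        for img in truth:
            for _, box in img.lesions:
                assert 0 <= box.x_min < box.x_max <= img.width
                assert 0 <= box.y_min < box.y_max <= img.height

    def test_no_positives_means_no_boxes(self):
        truth = simulate_ground_truth(
            tiny_config(n_positive_per_label=0), seed=2
        )
        assert all(not t.lesions for t in truth)

    def test_same_seed_reproduces_exactly(self):
        a = simulate_ground_truth(tiny_config(), seed=3)
        b = simulate_ground_truth(tiny_config(), seed=3)
        assert a == b

    def test_incompatible_lesion_size_rejected(self):
        with pytest.raises(ValueError, match="lesion"):
            SimulationConfig(image_width=64, image_height=64, lesion_max_side=128)


class TestAnnotators:
    def test_noiseless_annotators_reproduce_truth_and_full_support(self):
        config = tiny_config(
            annotators=(AnnotatorProfile(jitter_sd=0.0),) * 3
        )
        truth = simulate_ground_truth(config, seed=4)
        annotations = simulate_annotators(truth, config, seed=5)
        for img in truth:
            findings = consensus_findings(annotations[img.image_id])
            assert {(f.label, f.box) for f in findings} == set(img.lesions)
            assert all(f.support == 3 for f in findings)

    def test_one_blind_annotator_still_leaves_a_majority(self):
        config = tiny_config(
            annotators=(
                AnnotatorProfile(jitter_sd=0.0),
                AnnotatorProfile(jitter_sd=0.0),
                AnnotatorProfile(jitter_sd=0.0, miss_prob=1.0),
            )
        )
        truth = simulate_ground_truth(config, seed=6)
        annotations = simulate_annotators(truth, config, seed=7)
        for img in truth:
            findings = consensus_findings(annotations[img.image_id])
            assert {(f.label, f.box) for f in findings} == set(img.lesions)
            assert all(f.support == 2 for f in findings)


class TestDetections:
    def test_ideal_detectors_reproduce_truth(self):
        config = tiny_config(
            detectors=tuple(
                DetectorProfile(sensitivity=1.0, fp_rate=0.0, jitter_sd=0.0)
                for _ in range(5)
            ),
            shared_fp_rate=0.0,
        )
        truth = simulate_ground_truth(config, seed=8)
        detections = simulate_detections(truth, config, seed=9)
        for img in truth:
            dets = detections[img.image_id]
            assert len(dets) == 5 * len(img.lesions)
            for label, box in img.lesions:
                assert {d.model_id for d in dets if d.box == box} == {1, 2, 3, 4, 5}

    def test_per_model_sensitivity_recovered(self):
        config = SimulationConfig(
            n_positive_per_label=80,
            n_negative_per_label=0,
            codetection_correlation=0.5,
        )
        truth = simulate_ground_truth(config, seed=10)
        detections = simulate_detections(truth, config, seed=11)
        n_lesions = sum(len(t.lesions) for t in truth)
        for m, profile in enumerate(config.detectors, start=1):
            hits = sum(
                any(
                    d.model_id == m and d.label is lab
                    for d in detections[t.image_id]
                )
                for t in truth
                for lab, _ in t.lesions
            )
            lo, hi = stats.binom.interval(0.999, n_lesions, profile.sensitivity)
            assert lo <= hits <= hi

    def test_uncorrelated_false_positives_are_independent_across_models(self):
        """With no shared distractor sites, per-image FP presence of any
        two models shows no association (chi-square on the 2x2 table)."""
        config = SimulationConfig(
            n_positive_per_label=0,
            n_negative_per_label=600,
            detectors=tuple(DetectorProfile(fp_rate=0.7) for _ in range(5)),
            shared_fp_rate=0.0,
        )
        truth = simulate_ground_truth(config, seed=12)
        detections = simulate_detections(truth, config, seed=13)
        present = np.array(
            [
                [any(d.model_id == m for d in detections[t.image_id]) for m in (1, 2)]
                for t in truth
            ]
        )
        table = [
            [np.sum(present[:, 0] & present[:, 1]), np.sum(present[:, 0] & ~present[:, 1])],
            [np.sum(~present[:, 0] & present[:, 1]), np.sum(~present[:, 0] & ~present[:, 1])],
        ]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_scores_in_unit_interval(self, small_study):
        for dets in small_study.detections.values():
            for d in dets:
                assert 0.0 <= d.score <= 1.0


class TestReaders:
    def test_perfect_readers_agree_with_truth(self):
        config = tiny_config(
            unaided=ReaderConditionProfile(
                sensitivity=1.0, specificity=1.0, auc=0.95,
                time_mean_s=20.0, time_sd_s=1.0, operating_sd=0.0,
            ),
        )
        pool = simulate_reader_pool(config, seed=14)
        records = simulate_readers(pool, config, seed=15)
        truth = {t.image_id: t.positive_labels for t in pool}
        for r in records:
            if r.condition == "unaided":
                assert r.call == (r.label in truth[r.image_id])

    def test_reading_times_positive_and_condition_separated(self, small_study):
        times = {"unaided": [], "aided": []}
        for r in small_study.reader_records:
            assert r.time_s > 0
            times[r.condition].append(r.time_s)
        assert np.mean(times["aided"]) < np.mean(times["unaided"])


class TestStudyDeterminism:
    def test_same_seed_same_study(self, small_config):
        a = simulate_study(small_config, 99)
        b = simulate_study(small_config, 99)
        assert a.truth == b.truth
        assert a.annotations == b.annotations
        assert a.detections == b.detections
        assert a.reader_records == b.reader_records
        assert a.metadata.equals(b.metadata)

    def test_different_seeds_differ(self, small_config):
        a = simulate_study(small_config, 99)
        b = simulate_study(small_config, 100)
        assert a.detections != b.detections

    def test_evaluation_sets_are_positives_plus_shared_negatives(self, small_study):
        sets = small_study.evaluation_sets()
        negatives = {t.image_id for t in small_study.truth if not t.lesions}
        for label, ids in sets.items():
            assert len(ids) == 40 + 80
            assert negatives <= set(ids)

    def test_metadata_mix_recovers_configured_shares(self):
        study = simulate_study(tiny_config(n_negative_per_label=400), 16)
        meta = study.metadata
        shares = meta["manufacturer"].value_counts(normalize=True)
        for name, share in study.config.demographics.manufacturer_shares.items():
            se = np.sqrt(share * (1 - share) / len(meta))
            assert abs(shares.get(name, 0.0) - share) < 4 * se
        female = (meta["sex"] == "F").mean()
        assert abs(female - 0.545) < 4 * np.sqrt(0.25 / len(meta))
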
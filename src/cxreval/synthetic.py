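"""Synthetic chest-radiograph study generator.

Emulates the statistical structure of a two-phase CXR evaluation study
without any pixel data: a standalone set of per-pathology positive and
negative images with true lesion boxes, three annotators who redraw the
lesions with localization jitter, five detector models with configurable
sensitivity / false-positive / score characteristics and correlated
co-detection, and nine readers interpreting a separate case pool with and
without AI assistance.

All randomness flows from one seed through :class:`numpy.random.SeedSequence`
spawns, so identical config + seed reproduces the study exactly.

Co-detection across detector models uses a Gaussian copula: each lesion
carries a shared standard-normal "difficulty" latent, each model adds an
independent component weighted by the configured correlation, and the
model detects the lesion when the resulting normal quantile falls below
its sensitivity.  Marginal per-model detection probability is exactly the
configured sensitivity for any correlation.  False positives have an
independent Poisson component per model plus shared "distractor" sites
that several models may fire on, which is what lets a majority vote still
emit false positives the way real, correlated detectors do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import PathologyLabel, PixelBox
from .ensemble import Detection
from .gt_consensus import Annotation
from .reader_study import ReaderRecord

__all__ = [
    "DetectorProfile",
    "AnnotatorProfile",
    "ReaderConditionProfile",
    "Demographics",
    "SimulationConfig",
    "TruthImage",
    "simulate_ground_truth",
    "simulate_annotators",
    "simulate_detections",
    "simulate_readers",
    "simulate_study",
    "SimulatedStudy",
]

LABELS = tuple(PathologyLabel)


@dataclass(frozen=True)
class DetectorProfile:
    """Operating characteristics of one object-detection model.

    ``fp_rate`` is the Poisson mean of model-specific (independent) false
    boxes per image; shared false positives are configured study-wide.
    Scores are Beta-distributed, separately for true and false boxes.
    """

    sensitivity: float = 0.96
    fp_rate: float = 0.15
    jitter_sd: float = 6.0
    tp_score: tuple[float, float] = (8.0, 2.0)
    fp_score: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("rates and jitter must be non-negative")


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behaviour of one ground-truthing radiologist.

    Defaults model experienced annotators: boxes are redrawn with a few
    pixels of jitter but lesions are neither missed nor invented, so the
    2-of-3 consensus recovers the designed truth exactly.
    """

    jitter_sd: float = 4.0
    miss_prob: float = 0.0
    spurious_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0 or not 0.0 <= self.spurious_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ReaderConditionProfile:
    """Population operating point of the readers in one condition.

    ``sensitivity``/``specificity`` are per-anomaly call probabilities,
    ``auc`` the target rank AUC of the per-image confidences, and
    ``time_mean_s``/``time_sd_s`` the between-reader mean and SD of the
    per-image reading time (log-normal within reader).  ``operating_sd``
    and ``auc_sd`` are between-reader SDs of the operating point and AUC.
    """

    sensitivity: float
    specificity: float
    auc: float
    time_mean_s: float
    time_sd_s: float
    operating_sd: float = 0.02
    auc_sd: float = 0.05
    time_cv_within: float = 0.35


@dataclass(frozen=True)
class Demographics:
    """Metadata mix for the simulated standalone set."""

    age_mean: float = 49.9
    age_sd: float = 23.0
    female_fraction: float = 0.545
    manufacturer_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "GMM/Primax": 0.17,
            "Fujifilm": 0.11,
            "Shimadzu": 0.38,
            "Canon": 0.28,
            "Medecom": 0.06,
        }
    )


def _default_detectors() -> tuple[DetectorProfile, ...]:
    # five models sharing an architecture but trained from different
    # initialisations: similar, not identical, operating points
    return (
        DetectorProfile(sensitivity=0.955),
        DetectorProfile(sensitivity=0.960),
        DetectorProfile(sensitivity=0.965),
        DetectorProfile(sensitivity=0.958),
        DetectorProfile(sensitivity=0.962),
    )


def _default_reader_mix() -> dict[PathologyLabel, int]:
    # per-anomaly positive counts in the reader-study case pool
    return {
        PathologyLabel.CONSOLIDATION: 77,
        PathologyLabel.PLEURAL_EFFUSION: 60,
        PathologyLabel.PNEUMOTHORAX: 32,
        PathologyLabel.CARDIOMEGALY: 16,
        PathologyLabel.ACUTE_PULMONARY_EDEMA: 37,
        PathologyLabel.PULMONARY_NODULE: 43,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterization of a synthetic study.

    The defaults encode the study composition the analysis expects: 500
    positive and 1000 negative images per pathology in the standalone
    set, five detector models, three annotators, and nine readers whose
    aided/unaided operating points and reading-time distributions follow
    the reader-study summary table.
    """

    n_positive_per_label: int = 500
    n_negative_per_label: int = 1000
    image_width: int = 1024
    image_height: int = 1024
    lesion_min_side: int = 48
    lesion_max_side: int = 384
    detectors: tuple[DetectorProfile, ...] = field(default_factory=_default_detectors)
    codetection_correlation: float = 0.8
    shared_fp_rate: float = 1.0
    shared_fp_fire_prob: float = 0.9
    annotators: tuple[AnnotatorProfile, ...] = (
        AnnotatorProfile(),
        AnnotatorProfile(),
        AnnotatorProfile(),
    )
    n_readers: int = 9
    unaided: ReaderConditionProfile = ReaderConditionProfile(
        sensitivity=0.769,
        specificity=0.946,
        auc=0.759,
        time_mean_s=22.9,
        time_sd_s=2.3,
        auc_sd=0.07,
    )
    aided: ReaderConditionProfile = ReaderConditionProfile(
        sensitivity=0.857,
        specificity=0.974,
        auc=0.88,
        time_mean_s=14.7,
        time_sd_s=1.3,
        auc_sd=0.05,
    )
    reader_positive_mix: Mapping[PathologyLabel, int] = field(
        default_factory=_default_reader_mix
    )
    n_reader_negatives: int = 640
    demographics: Demographics = Demographics()

    def __post_init__(self) -> None:
        if self.n_positive_per_label < 0 or self.n_negative_per_label < 0:
            raise ValueError("image counts must be non-negative")
        if not 0.0 <= self.codetection_correlation <= 1.0:
            raise ValueError("codetection_correlation must lie in [0, 1]")
        if self.lesion_max_side > min(self.image_width, self.image_height):
            raise ValueError("lesion size distribution incompatible with image size")
        if self.lesion_min_side < 1 or self.lesion_min_side > self.lesion_max_side:
            raise ValueError("invalid lesion side bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detectors"] = [asdict(p) for p in self.detectors]
        d["annotators"] = [asdict(p) for p in self.annotators]
        d["reader_positive_mix"] = {
            PathologyLabel(k).value: v for k, v in self.reader_positive_mix.items()
        }
        d["demographics"]["manufacturer_shares"] = dict(
            self.demographics.manufacturer_shares
        )
        return d


@dataclass(frozen=True)
class TruthImage:
    """A simulated image: id, size, and its true lesion boxes."""

    image_id: str
    width: int
    height: int
    lesions: tuple[tuple[PathologyLabel, PixelBox], ...]

    @property
    def positive_labels(self) -> frozenset[PathologyLabel]:
        return frozenset(lab for lab, _ in self.lesions)


def _random_box(
    config: SimulationConfig, rng: np.random.Generator
) -> PixelBox:
    """A lesion-sized box placed uniformly inside the image bounds.

    Side lengths are log-uniform between the configured bounds.
    """
    lo, hi = math.log(config.lesion_min_side), math.log(config.lesion_max_side)
    w = int(round(math.exp(rng.uniform(lo, hi))))
    h = int(round(math.exp(rng.uniform(lo, hi))))
    w = min(max(w, 1), config.image_width)
    h = min(max(h, 1), config.image_height)
    x = int(rng.integers(0, config.image_width - w + 1))
    y = int(rng.integers(0, config.image_height - h + 1))
    return PixelBox(x, y, x + w, y + h)


def _jitter_box(
    box: PixelBox,
    sd: float,
    width: int,
    height: int,
    rng: np.random.Generator,
) -> PixelBox:
    """Perturb each corner by rounded N(0, sd), clipped to the image and
    repaired to stay a valid (non-degenerate) box."""
    if sd == 0:
        return box
    dx0, dy0, dx1, dy1 = np.round(rng.normal(0.0, sd, size=4)).astype(int)
    x0 = min(max(box.x_min + int(dx0), 0), width - 1)
    y0 = min(max(box.y_min + int(dy0), 0), height - 1)
    x1 = min(max(box.x_max + int(dx1), x0 + 1), width)
    y1 = min(max(box.y_max + int(dy1), y0 + 1), height)
    return PixelBox(x0, y0, x1, y1)


def simulate_ground_truth(
    config: SimulationConfig, seed: int | np.random.Generator
) -> list[TruthImage]:
    """Generate the standalone-set truth: per pathology,
    ``n_positive_per_label`` images with one lesion of that pathology,
    plus ``n_negative_per_label`` lesion-free images shared across
    pathologies."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    images: list[TruthImage] = []
    for label in LABELS:
        for i in range(config.n_positive_per_label):
            box = _random_box(config, rng)
            images.append(
                TruthImage(
                    image_id=f"pos_{label.value}_{i:04d}",
                    width=config.image_width,
                    height=config.image_height,
                    lesions=((label, box),),
                )
            )
    for i in range(config.n_negative_per_label):
        images.append(
            TruthImage(
                image_id=f"neg_{i:04d}",
                width=config.image_width,
                height=config.image_height,
                lesions=(),
            )
        )
    return images


def simulate_annotators(
    truth: Sequence[TruthImage],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> dict[str, list[Annotation]]:
    """Each annotator redraws every true lesion with jitter, misses it
    with their miss probability, and adds spurious boxes at their
    spurious-box probability."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: dict[str, list[Annotation]] = {}
    for img in truth:
        anns: list[Annotation] = []
        for aid, profile in enumerate(config.annotators, start=1):
            for label, box in img.lesions:
                if rng.random() < profile.miss_prob:
                    continue
                anns.append(
                    Annotation(
                        box=_jitter_box(box, profile.jitter_sd, img.width, img.height, rng),
                        label=label,
                        annotator_id=aid,
                    )
                )
            if rng.random() < profile.spurious_prob:
                anns.append(
                    Annotation(
                        box=_random_box(config, rng),
                        label=LABELS[int(rng.integers(0, len(LABELS)))],
                        annotator_id=aid,
                    )
                )
        out[img.image_id] = anns
    return out


def _beta_score(params: tuple[float, float], rng: np.random.Generator) -> float:
    s = float(rng.beta(*params))
    return min(max(s, 0.0), 1.0)


def simulate_detections(
    truth: Sequence[TruthImage],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> dict[str, list[Detection]]:
    """Generate the five models' raw outputs for every image.

    True lesions are detected through the Gaussian-copula co-detection
    mechanism (marginal rate = each model's sensitivity); false boxes
    combine per-model independent Poisson noise with shared distractor
    sites fired on by each model with ``shared_fp_fire_prob``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rho = config.codetection_correlation
    n_models = len(config.detectors)
    out: dict[str, list[Detection]] = {}
    for img in truth:
        dets: list[Detection] = []
        for label, box in img.lesions:
            z = rng.normal()
            eps = rng.normal(size=n_models)
            w = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
            for m, profile in enumerate(config.detectors, start=1):
                if norm.cdf(w[m - 1]) < profile.sensitivity:
                    dets.append(
                        Detection(
                            box=_jitter_box(
                                box, profile.jitter_sd, img.width, img.height, rng
                            ),
                            score=_beta_score(profile.tp_score, rng),
                            label=label,
                            model_id=m,
                        )
                    )
        # shared distractor sites: several models may fire on the same spot
        for _ in range(rng.poisson(config.shared_fp_rate)):
            site = _random_box(config, rng)
            site_label = LABELS[int(rng.integers(0, len(LABELS)))]
            for m, profile in enumerate(config.detectors, start=1):
                if rng.random() < config.shared_fp_fire_prob:
                    dets.append(
                        Detection(
                            box=_jitter_box(
                                site, profile.jitter_sd, img.width, img.height, rng
                            ),
                            score=_beta_score(profile.fp_score, rng),
                            label=site_label,
                            model_id=m,
                        )
                    )
        # model-specific independent false positives
        for m, profile in enumerate(config.detectors, start=1):
            for _ in range(rng.poisson(profile.fp_rate)):
                dets.append(
                    Detection(
                        box=_random_box(config, rng),
                        score=_beta_score(profile.fp_score, rng),
                        label=LABELS[int(rng.integers(0, len(LABELS)))],
                        model_id=m,
                    )
                )
        out[img.image_id] = dets
    return out


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def simulate_readers(
    truth: Sequence[TruthImage],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> list[ReaderRecord]:
    """Simulate the two reading sessions over the reader case pool.

    The pool is split into two halves; every reader reads the first half
    unaided and the second aided.  Each reader draws a personal operating
    point, AUC, and mean reading time around the condition profile, then
    calls each image-label pair at that operating point.  Confidences are
    drawn from a binormal model whose separation is calibrated to the
    reader's target AUC; they are coupled to the calls only through the
    ground truth, which is the only way to honour an operating point that
    lies above the confidence ROC curve.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = list(truth)
    half = len(order) // 2
    sessions = {"unaided": order[:half], "aided": order[half:]}
    records: list[ReaderRecord] = []
    for reader_id in range(1, config.n_readers + 1):
        for condition in ("unaided", "aided"):
            profile = config.unaided if condition == "unaided" else config.aided
            sens = _truncated_normal(profile.sensitivity, profile.operating_sd, 0, 1, rng)
            spec = _truncated_normal(profile.specificity, profile.operating_sd, 0, 1, rng)
            auc = _truncated_normal(profile.auc, profile.auc_sd, 0.5, 1, rng)
            d = math.sqrt(2.0) * float(norm.ppf(auc))
            mean_time = _truncated_normal(
                profile.time_mean_s, profile.time_sd_s, 0.1, math.inf, rng
            )
            cv = profile.time_cv_within
            sigma2 = math.log(1.0 + cv**2)
            mu = math.log(mean_time) - sigma2 / 2.0
            for img in sessions[condition]:
                time_s = float(rng.lognormal(mu, math.sqrt(sigma2)))
                positives = img.positive_labels
                for label in LABELS:
                    is_pos = label in positives
                    call = rng.random() < (sens if is_pos else 1.0 - spec)
                    conf = float(norm.cdf(rng.normal(d if is_pos else 0.0, 1.0)))
                    records.append(
                        ReaderRecord(
                            reader_id=reader_id,
                            condition=condition,
                            image_id=img.image_id,
                            label=label,
                            call=bool(call),
                            confidence=conf,
                            time_s=time_s,
                        )
                    )
    return records


def simulate_reader_pool(
    config: SimulationConfig, seed: int | np.random.Generator
) -> list[TruthImage]:
    """Truth for the reader-study case pool: per-anomaly positive counts
    from ``reader_positive_mix`` plus ``n_reader_negatives`` normals,
    interleaved so both reading sessions see a similar case mix."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    images: list[TruthImage] = []
    for label in LABELS:
        n = int(config.reader_positive_mix.get(label, 0))
        for i in range(n):
            images.append(
                TruthImage(
                    image_id=f"rdr_pos_{label.value}_{i:03d}",
                    width=config.image_width,
                    height=config.image_height,
                    lesions=((label, _random_box(config, rng)),),
                )
            )
    for i in range(config.n_reader_negatives):
        images.append(
            TruthImage(
                image_id=f"rdr_neg_{i:03d}",
                width=config.image_width,
                height=config.image_height,
                lesions=(),
            )
        )
    perm = rng.permutation(len(images))
    return [images[int(i)] for i in perm]


def simulate_metadata(
    truth: Sequence[TruthImage],
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Demographic and acquisition metadata for each image."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    demo = config.demographics
    n = len(truth)
    ages = np.clip(rng.normal(demo.age_mean, demo.age_sd, size=n), 0, 105)
    sexes = np.where(rng.random(n) < demo.female_fraction, "F", "M")
    names = list(demo.manufacturer_shares)
    shares = np.array([demo.manufacturer_shares[k] for k in names], dtype=float)
    shares = shares / shares.sum()
    manufacturers = rng.choice(names, size=n, p=shares)
    return pd.DataFrame(
        {
            "image_id": [img.image_id for img in truth],
            "age": np.round(ages, 1),
            "sex": sexes,
            "manufacturer": manufacturers,
        }
    )


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    seed: int
    truth: list[TruthImage]
    annotations: dict[str, list[Annotation]]
    detections: dict[str, list[Detection]]
    reader_pool: list[TruthImage]
    reader_records: list[ReaderRecord]
    metadata: pd.DataFrame

    @property
    def reader_truth(self) -> dict[str, frozenset[PathologyLabel]]:
        return {img.image_id: img.positive_labels for img in self.reader_pool}

    def evaluation_sets(self) -> dict[PathologyLabel, list[str]]:
        """Per pathology, the designed evaluation set: that pathology's
        positive images plus the shared lesion-free negatives."""
        negatives = [img.image_id for img in self.truth if not img.lesions]
        sets: dict[PathologyLabel, list[str]] = {}
        for label in LABELS:
            positives = [
                img.image_id
                for img in self.truth
                if label in img.positive_labels
            ]
            sets[label] = positives + negatives
        return sets


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Compose the generators into one complete, reproducible study."""
    ss = np.random.SeedSequence(seed)
    s_truth, s_ann, s_det, s_pool, s_read, s_meta = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]
    truth = simulate_ground_truth(config, s_truth)
    annotations = simulate_annotators(truth, config, s_ann)
    detections = simulate_detections(truth, config, s_det)
    reader_pool = simulate_reader_pool(config, s_pool)
    reader_records = simulate_readers(reader_pool, config, s_read)
    metadata = simulate_metadata(truth, config, s_meta)
    return SimulatedStudy(
        config=config,
        seed=seed,
        truth=truth,
        annotations=annotations,
        detections=detections,
        reader_pool=reader_pool,
        reader_records=reader_records,
        metadata=metadata,
    )
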
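"""On-disk formats: COCO-style detection/annotation JSON, reader CSV,
study bundles, and simulation configs.

Boxes are serialized as ``[x, y, width, height]`` for COCO-dialect
familiarity and converted to corner form at this boundary; everything
in memory is corner-form :class:`~cxreval.geometry.PixelBox`.  Parsing is
strict by default — a malformed record aborts with file context — because
silently dropped records corrupt confusion counts; lenient mode skips bad
records and logs how many were dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .ensemble import Detection
from .geometry import PathologyLabel, PixelBox
from .gt_consensus import Annotation, GroundTruthFinding
from .reader_study import CONDITIONS, ReaderRecord
from .synthetic import (
    AnnotatorProfile,
    Demographics,
    DetectorProfile,
    ReaderConditionProfile,
    SimulatedStudy,
    SimulationConfig,
)

logger = logging.getLogger("cxreval")

__all__ = [
    "FormatError",
    "ImageInfo",
    "StudyBundle",
    "read_detections",
    "write_detections",
    "read_annotations",
    "write_annotations",
    "read_ground_truth",
    "write_ground_truth",
    "read_reader_results",
    "write_reader_results",
    "load_config",
    "save_config",
    "save_study",
    "load_study",
]


class FormatError(ValueError):
    """A file failed validation; the message names the offending record."""


@dataclass(frozen=True)
class ImageInfo:
    id: str
    width: int
    height: int


def _box_to_coco(box: PixelBox) -> list[int]:
    return [box.x_min, box.y_min, box.width, box.height]


def _box_from_coco(bbox: Sequence, where: str) -> PixelBox:
    if len(bbox) != 4:
        raise FormatError(f"{where}: bbox must have 4 entries, got {bbox!r}")
    x, y, w, h = (int(v) for v in bbox)
    if w <= 0 or h <= 0:
        raise FormatError(f"{where}: non-positive bbox width/height in {bbox!r}")
    try:
        return PixelBox(x, y, x + w, y + h)
    except ValueError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def _label(value, where: str) -> PathologyLabel:
    try:
        return PathologyLabel(value)
    except ValueError as exc:
        raise FormatError(f"{where}: unknown category {value!r}") from exc


def _read_box_file(path, record_key: str, strict: bool):
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    images = [
        ImageInfo(str(i["id"]), int(i["width"]), int(i["height"]))
        for i in payload.get("images", [])
    ]
    known = {i.id for i in images}
    records = payload.get(record_key, [])
    good, skipped = [], 0
    for k, rec in enumerate(records):
        where = f"{path.name}:{record_key}[{k}]"
        try:
            if str(rec["image_id"]) not in known:
                raise FormatError(f"{where}: image_id {rec['image_id']!r} not in manifest")
            good.append((where, rec))
        except FormatError:
            if strict:
                raise
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed records", path, skipped)
    return images, good, skipped


def write_detections(
    path,
    images: Sequence[ImageInfo],
    detections: Mapping[str, Sequence[Detection]],
) -> None:
    payload = {
        "images": [dataclasses.asdict(i) for i in images],
        "detections": [
            {
                "image_id": image_id,
                "model_id": d.model_id,
                "category": d.label.value,
                "bbox": _box_to_coco(d.box),
                "score": d.score,
            }
            for image_id in sorted(detections)
            for d in detections[image_id]
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_detections(
    path, strict: bool = True
) -> tuple[list[ImageInfo], dict[str, list[Detection]]]:
    images, records, skipped = _read_box_file(path, "detections", strict)
    out: dict[str, list[Detection]] = {i.id: [] for i in images}
    for where, rec in records:
        try:
            score = float(rec["score"])
            if not 0.0 <= score <= 1.0:
                raise FormatError(f"{where}: score outside [0, 1]: {score}")
            det = Detection(
                box=_box_from_coco(rec["bbox"], where),
                score=score,
                label=_label(rec["category"], where),
                model_id=int(rec["model_id"]),
            )
        except (FormatError, ValueError, KeyError) as exc:
            if strict:
                raise FormatError(f"{where}: {exc}") from exc
            skipped += 1
            continue
        out[str(rec["image_id"])].append(det)
    if skipped:
        logger.warning("%s: skipped %d malformed records", path, skipped)
    return images, out


def write_annotations(
    path,
    images: Sequence[ImageInfo],
    annotations: Mapping[str, Sequence[Annotation]],
) -> None:
    payload = {
        "images": [dataclasses.asdict(i) for i in images],
        "annotations": [
            {
                "image_id": image_id,
                "annotator_id": a.annotator_id,
                "category": a.label.value,
                "bbox": _box_to_coco(a.box),
            }
            for image_id in sorted(annotations)
            for a in annotations[image_id]
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_annotations(
    path, strict: bool = True
) -> tuple[list[ImageInfo], dict[str, list[Annotation]]]:
    images, records, skipped = _read_box_file(path, "annotations", strict)
    out: dict[str, list[Annotation]] = {i.id: [] for i in images}
    for where, rec in records:
        try:
            ann = Annotation(
                box=_box_from_coco(rec["bbox"], where),
                label=_label(rec["category"], where),
                annotator_id=int(rec["annotator_id"]),
            )
        except (FormatError, ValueError, KeyError) as exc:
            if strict:
                raise FormatError(f"{where}: {exc}") from exc
            skipped += 1
            continue
        out[str(rec["image_id"])].append(ann)
    if skipped:
        logger.warning("%s: skipped %d malformed records", path, skipped)
    return images, out


def write_ground_truth(
    path,
    images: Sequence[ImageInfo],
    findings: Mapping[str, Sequence[GroundTruthFinding]],
) -> None:
    payload = {
        "images": [dataclasses.asdict(i) for i in images],
        "findings": [
            {
                "image_id": image_id,
                "category": f.label.value,
                "bbox": _box_to_coco(f.box),
                "support": f.support,
            }
            for image_id in sorted(findings)
            for f in findings[image_id]
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_ground_truth(
    path, strict: bool = True
) -> tuple[list[ImageInfo], dict[str, list[GroundTruthFinding]]]:
    images, records, skipped = _read_box_file(path, "findings", strict)
    out: dict[str, list[GroundTruthFinding]] = {i.id: [] for i in images}
    for where, rec in records:
        try:
            f = GroundTruthFinding(
                box=_box_from_coco(rec["bbox"], where),
                label=_label(rec["category"], where),
                support=int(rec["support"]),
            )
        except (FormatError, ValueError, KeyError) as exc:
            if strict:
                raise FormatError(f"{where}: {exc}") from exc
            skipped += 1
            continue
        out[str(rec["image_id"])].append(f)
    if skipped:
        logger.warning("%s: skipped %d malformed records", path, skipped)
    return images, out


READER_COLUMNS = [
    "reader_id",
    "condition",
    "image_id",
    "label",
    "call",
    "confidence",
    "time_s",
]


def write_reader_results(path, records: Sequence[ReaderRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "reader_id": r.reader_id,
                "condition": r.condition,
                "image_id": r.image_id,
                "label": r.label.value,
                "call": int(r.call),
                "confidence": r.confidence,
                "time_s": r.time_s,
            }
            for r in records
        ],
        columns=READER_COLUMNS,
    )
    # %.17g round-trips float64 exactly, keeping write->read an identity
    df.to_csv(path, index=False, float_format="%.17g")


def read_reader_results(path, strict: bool = True) -> list[ReaderRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = [c for c in READER_COLUMNS if c != "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_conf = "confidence" in df.columns
    if not has_conf:
        logger.warning("%s: no confidence column; reader AUC unavailable", path)
    records, skipped = [], 0
    for k, row in enumerate(df.itertuples(index=False)):
        where = f"{Path(path).name}:row {k}"
        try:
            condition = str(row.condition)
            if condition not in CONDITIONS:
                raise FormatError(f"{where}: unknown condition {condition!r}")
            conf = getattr(row, "confidence", None)
            if conf is not None and pd.isna(conf):
                conf = None
            records.append(
                ReaderRecord(
                    reader_id=int(row.reader_id),
                    condition=condition,
                    image_id=str(row.image_id),
                    label=_label(row.label, where),
                    call=bool(int(row.call)),
                    confidence=None if conf is None else float(conf),
                    time_s=float(row.time_s),
                )
            )
        except (FormatError, ValueError) as exc:
            if strict:
                raise FormatError(f"{where}: {exc}") from exc
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    return records


# --- simulation config ----------------------------------------------------


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a (possibly partial) mapping;
    omitted fields keep their defaults."""
    d = dict(d)
    kwargs: dict = {}
    if "detectors" in d:
        kwargs["detectors"] = tuple(DetectorProfile(**{
            **p, "tp_score": tuple(p.get("tp_score", (8.0, 2.0))),
            "fp_score": tuple(p.get("fp_score", (2.0, 5.0))),
        }) for p in d.pop("detectors"))
    if "annotators" in d:
        kwargs["annotators"] = tuple(
            AnnotatorProfile(**p) for p in d.pop("annotators")
        )
    for cond in ("unaided", "aided"):
        if cond in d:
            kwargs[cond] = ReaderConditionProfile(**d.pop(cond))
    if "reader_positive_mix" in d:
        kwargs["reader_positive_mix"] = {
            PathologyLabel(k): int(v) for k, v in d.pop("reader_positive_mix").items()
        }
    if "demographics" in d:
        kwargs["demographics"] = Demographics(**d.pop("demographics"))
    kwargs.update(d)
    return SimulationConfig(**kwargs)


def load_config(path) -> SimulationConfig:
    """Read a YAML or JSON simulation config."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False), encoding="utf-8"
    )


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --- study bundles --------------------------------------------------------

BUNDLE_FILES = {
    "manifest": "manifest.json",
    "detections": "detections.json",
    "annotations": "annotations.json",
    "ground_truth": "ground_truth.json",
    "reader_ground_truth": "reader_ground_truth.json",
    "reader_results": "reader_results.csv",
    "metadata": "metadata.csv",
}


@dataclass
class StudyBundle:
    """A complete on-disk study, parsed back into memory."""

    manifest: dict
    images: list[ImageInfo]
    detections: dict[str, list[Detection]]
    annotations: dict[str, list[Annotation]]
    findings: dict[str, list[GroundTruthFinding]]
    reader_truth: dict[str, frozenset[PathologyLabel]] = field(default_factory=dict)
    reader_records: list[ReaderRecord] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def evaluation_sets(self) -> dict[PathologyLabel, list[str]]:
        return {
            PathologyLabel(k): list(v)
            for k, v in self.manifest["evaluation_sets"].items()
        }


def save_study(study: SimulatedStudy, outdir) -> None:
    """Write a simulated study as a full bundle.

    The consensus reference standard is rebuilt from the annotator boxes
    (not copied from the simulator's hidden truth), so the saved ground
    truth is exactly what the consensus protocol would produce.
    """
    from .pipeline import consensus_study  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = [ImageInfo(t.image_id, t.width, t.height) for t in study.truth]
    pool_images = [
        ImageInfo(t.image_id, t.width, t.height) for t in study.reader_pool
    ]
    findings = consensus_study(
        study.annotations, n_annotators=len(study.config.annotators)
    )
    reader_findings = {
        t.image_id: [
            GroundTruthFinding(box=box, label=lab, support=len(study.config.annotators))
            for lab, box in t.lesions
        ]
        for t in study.reader_pool
    }
    manifest = {
        "study_id": f"synthetic-{study.seed}",
        "n_images": len(images),
        "n_reader_images": len(pool_images),
        "labels": [lab.value for lab in PathologyLabel],
        "seed": study.seed,
        "config": study.config.to_dict(),
        "config_hash": config_hash(study.config),
        "evaluation_sets": {
            lab.value: ids for lab, ids in study.evaluation_sets().items()
        },
    }
    (outdir / BUNDLE_FILES["manifest"]).write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    write_detections(outdir / BUNDLE_FILES["detections"], images, study.detections)
    write_annotations(outdir / BUNDLE_FILES["annotations"], images, study.annotations)
    write_ground_truth(outdir / BUNDLE_FILES["ground_truth"], images, findings)
    write_ground_truth(
        outdir / BUNDLE_FILES["reader_ground_truth"], pool_images, reader_findings
    )
    write_reader_results(
        outdir / BUNDLE_FILES["reader_results"], study.reader_records
    )
    study.metadata.to_csv(outdir / BUNDLE_FILES["metadata"], index=False)


def load_study(bundle_dir, strict: bool = True) -> StudyBundle:
    """Read a study bundle back from disk."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads(
        (bundle_dir / BUNDLE_FILES["manifest"]).read_text(encoding="utf-8")
    )
    images, detections = read_detections(
        bundle_dir / BUNDLE_FILES["detections"], strict
    )
    _, annotations = read_annotations(
        bundle_dir / BUNDLE_FILES["annotations"], strict
    )
    _, findings = read_ground_truth(
        bundle_dir / BUNDLE_FILES["ground_truth"], strict
    )
    reader_truth: dict[str, frozenset[PathologyLabel]] = {}
    reader_records: list[ReaderRecord] = []
    rgt = bundle_dir / BUNDLE_FILES["reader_ground_truth"]
    if rgt.exists():
        _, rfind = read_ground_truth(rgt, strict)
        reader_truth = {
            image_id: frozenset(f.label for f in fs) for image_id, fs in rfind.items()
        }
    rres = bundle_dir / BUNDLE_FILES["reader_results"]
    if rres.exists():
        reader_records = read_reader_results(rres, strict)
    meta_path = bundle_dir / BUNDLE_FILES["metadata"]
    metadata = pd.read_csv(meta_path) if meta_path.exists() else None
    labels = set(manifest.get("labels", []))
    enum_values = {lab.value for lab in PathologyLabel}
    unknown = labels - enum_values
    if unknown:
        raise FormatError(f"manifest lists unknown labels: {sorted(unknown)}")
    return StudyBundle(
        manifest=manifest,
        images=images,
        detections=detections,
        annotations=annotations,
        findings=findings,
        reader_truth=reader_truth,
        reader_records=reader_records,
        metadata=metadata,
    )
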
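"""CSV readers/writers for every artifact the pipeline exchanges.

Formats (all plain text, frames 0-based, regions half-open ``[start, end)``):

* recording — wide CSV, one row per frame: ``frame`` then the 18 channel
  columns ``{lhip|rhip|back}_{acc|gyr}_{x|y|z}``; one file per subject;
* annotations — ``subject_id,event_id,activity_class,subtype,adl_kind,
  region_start_frame,region_end_frame,impact_frame,defective``;
* subject manifest — ``subject_id,cohort,severity,gait_speed`` with a JSON
  sidecar of ground-truth kinematic parameters;
* feature matrix — header row, 126 feature columns plus trailing labels;
* per-iteration report and comparison tables.

Writers round-trip to full precision (shortest-repr floats); readers
validate schema and invariants and raise descriptive errors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_extraction import FEATURE_COLUMNS
from .synthetic_data import (
    CHANNELS,
    Dataset,
    EventAnnotation,
    IMURecording,
    KinematicParams,
    SubjectProfile,
)


class FormatError(ValueError):
    pass


ANNOTATION_COLUMNS = (
    "subject_id",
    "event_id",
    "activity_class",
    "subtype",
    "adl_kind",
    "region_start_frame",
    "region_end_frame",
    "impact_frame",
    "defective",
)


def write_recording_csv(recording: IMURecording, path: str | Path) -> None:
    df = pd.DataFrame(recording.data.astype(np.float64), columns=list(CHANNELS))
    df.insert(0, "frame", np.arange(recording.n_frames))
    df.to_csv(path, index=False)


def read_recording_csv(path: str | Path, subject_id: str | None = None) -> IMURecording:
    df = pd.read_csv(path)
    expected = ["frame", *CHANNELS]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected[:3]}..., got {list(df.columns)[:3]}...")
    sid = subject_id if subject_id is not None else Path(path).stem
    return IMURecording(sid, df[list(CHANNELS)].to_numpy(dtype=np.float32))


def write_annotations_csv(annotations: list[EventAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "subject_id": a.subject_id,
                "event_id": a.event_id,
                "activity_class": a.activity_class,
                "subtype": a.subtype,
                "adl_kind": a.adl_kind if a.adl_kind is not None else "",
                "region_start_frame": a.region_start_frame,
                "region_end_frame": a.region_end_frame,
                "impact_frame": a.true_impact_frame if a.true_impact_frame is not None else "",
                "defective": int(a.defective),
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path, keep_default_na=False)
    if list(df.columns) != list(ANNOTATION_COLUMNS):
        raise FormatError(f"{path}: annotation header mismatch: {list(df.columns)}")
    out = []
    for _, r in df.iterrows():
        start, end = int(r.region_start_frame), int(r.region_end_frame)
        if start >= end:
            raise FormatError(
                f"{path}: event {r.event_id}: region_start_frame >= region_end_frame"
            )
        impact = None if r.impact_frame == "" else int(r.impact_frame)
        out.append(
            EventAnnotation(
                event_id=str(r.event_id),
                subject_id=str(r.subject_id),
                activity_class=str(r.activity_class),
                subtype=str(r.subtype),
                adl_kind=str(r.adl_kind) or None,
                region_start_frame=start,
                region_end_frame=end,
                true_impact_frame=impact,
                defective=bool(int(r.defective)),
            )
        )
    return out


def write_manifest(profiles: list[SubjectProfile], path: str | Path) -> None:
    """Subject manifest CSV plus a ``<stem>_kinematics.json`` sidecar of the
    ground-truth generator parameters."""
    path = Path(path)
    pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "cohort": p.cohort,
                "severity": p.severity,
                "gait_speed": p.gait_speed,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)
    sidecar = {p.subject_id: dataclasses.asdict(p.kinematics) for p in profiles}
    path.with_name(path.stem + "_kinematics.json").write_text(json.dumps(sidecar, indent=1))


def read_manifest(path: str | Path) -> list[SubjectProfile]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "cohort", "severity", "gait_speed"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    sidecar = path.with_name(path.stem + "_kinematics.json")
    kin = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return [
        SubjectProfile(
            str(r.subject_id),
            str(r.cohort),
            str(r.severity),
            float(r.gait_speed),
            KinematicParams(**kin.get(str(r.subject_id), {})),
        )
        for _, r in df.iterrows()
    ]


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(dataset.profiles, out / "subjects.csv")
    write_annotations_csv(dataset.annotations, out / "annotations.csv")
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for sid, rec in dataset.recordings.items():
        write_recording_csv(rec, rec_dir / f"{sid}.csv")


def read_dataset(in_dir: str | Path) -> Dataset:
    src = Path(in_dir)
    profiles = read_manifest(src / "subjects.csv")
    annotations = read_annotations_csv(src / "annotations.csv")
    recordings = {
        p.subject_id: read_recording_csv(src / "recordings" / f"{p.subject_id}.csv")
        for p in profiles
    }
    return Dataset(profiles, recordings, annotations)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("cohort", "activity_class", "subtype", "lead_time_ms", "subject_id", "event_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: feature matrix missing label column {col!r}")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature matrix missing {len(missing)} feature columns")
    return df


def write_windows_manifest(rows: list[dict], path: str | Path) -> None:
    cols = ["event_id", "lead_time_ms", "start_frame", "end_frame", "excluded", "exclusion_reason"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
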
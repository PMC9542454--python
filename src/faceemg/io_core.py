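"""Session I/O: CSV signal tables with JSON sidecars, schedule and rating CSVs.

On-disk layout of a cohort directory::

    <dir>/schedule.csv             video events (one row per subject x video)
    <dir>/ratings.csv              subject_id, video_id, valence, arousal
    <dir>/<subject>_<stage>.csv    time_s + one column per channel
    <dir>/<subject>_<stage>.json   {"subject_id": ..., "fs": ..., "stage": ...}

Signals are stored one CSV per subject per processing stage; the sidecar
JSON carries the metadata that the CSV cannot (sampling rate, stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CATEGORIES,
    CHANNELS,
    STUDY_CATEGORY_COUNTS,
    EmgRecording,
    FormatError,
    RatingRecord,
    SessionSchedule,
    SessionValidationError,
    VideoEvent,
    check_unique_ratings,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_ratings",
    "write_ratings",
    "read_schedule",
    "write_schedule",
    "validate_session",
    "Violation",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(recording: EmgRecording, csv_path: str | Path) -> Path:
    """Write a recording as ``<path>.csv`` plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"time_s": t})
    for ch in recording.channels:
        df[ch] = recording.channel(ch)
    df.to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "subject_id": recording.subject_id,
        "fs": recording.fs,
        "stage": recording.stage,
        "channels": list(recording.channels),
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> EmgRecording:
    """Read a signal CSV (time_s + channel columns) and its JSON sidecar."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    sidecar = _sidecar_path(csv_path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "fs", "stage"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    fs = float(meta["fs"])
    if fs <= 0:
        raise SessionValidationError(f"fs must be positive, got {fs}")

    df = pd.read_csv(csv_path)
    if "time_s" not in df.columns:
        raise FormatError(f"{csv_path}: missing required column 'time_s'")
    channels = tuple(meta.get("channels", CHANNELS))
    for ch in channels:
        if ch not in df.columns:
            raise FormatError(f"{csv_path}: missing channel column {ch!r}")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{csv_path}: time_s column is not strictly increasing")
    samples = np.vstack([df[ch].to_numpy(dtype=float) for ch in channels])
    return EmgRecording(
        subject_id=str(meta["subject_id"]),
        fs=fs,
        channels=channels,
        samples=samples,
        stage=str(meta["stage"]),
    )


def write_ratings(records: Sequence[RatingRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "video_id": r.video_id,
                "valence": r.valence,
                "arousal": r.arousal,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return path


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Read a ratings CSV; every row is validated against the 1-9 scale."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "video_id", "valence", "arousal"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                RatingRecord(
                    subject_id=str(row.subject_id),
                    video_id=str(row.video_id),
                    valence=int(row.valence),
                    arousal=int(row.arousal),
                )
            )
        except SessionValidationError as exc:
            raise SessionValidationError(f"{path}, row {i}: {exc}") from None
    check_unique_ratings(records)
    return records


def write_schedule(schedules: SessionSchedule | Sequence[SessionSchedule],
                   path: str | Path) -> Path:
    if isinstance(schedules, SessionSchedule):
        schedules = [schedules]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for sched in schedules:
        for ev in sched.events:
            rows.append(
                {
                    "subject_id": sched.subject_id,
                    "video_id": ev.video_id,
                    "category": ev.category,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                    "break_s": sched.break_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def read_schedule(path: str | Path) -> list[SessionSchedule]:
    """Read a schedule CSV; returns one SessionSchedule per subject."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "video_id", "category", "start_s", "end_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    schedules = []
    for subject_id, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("start_s")
        events = [
            VideoEvent(
                video_id=str(r.video_id),
                category=str(r.category),
                start_s=float(r.start_s),
                end_s=float(r.end_s),
            )
            for r in grp.itertuples(index=False)
        ]
        break_s = float(grp["break_s"].iloc[0]) if "break_s" in grp.columns else 10.0
        schedules.append(SessionSchedule(str(subject_id), events, break_s))
    return schedules


@dataclass(frozen=True)
class Violation:
    """One session-conformance problem found by :func:`validate_session`."""

    code: str
    message: str


def validate_session(
    recording: EmgRecording | None,
    schedule: SessionSchedule,
    ratings: Iterable[RatingRecord],
) -> list[Violation]:
    """Report (not raise) session-conformance problems.

    Checks: schedule events within the recording's duration; every video
    rated exactly once; study-conformant category counts (10 neutral,
    6 negative, 9 positive).
    """
    violations: list[Violation] = []
    if recording is not None:
        for ev in schedule.events:
            if ev.end_s > recording.duration_s + 1e-9:
                violations.append(
                    Violation(
                        "event_out_of_range",
                        f"event {ev.video_id} ends at {ev.end_s:.1f} s but the "
                        f"recording lasts {recording.duration_s:.1f} s",
                    )
                )
    ratings = list(ratings)
    rated = {(r.subject_id, r.video_id) for r in ratings}
    subject = schedule.subject_id
    for ev in schedule.events:
        if (subject, ev.video_id) not in rated:
            violations.append(
                Violation(
                    "missing_rating",
                    f"video {ev.video_id} has no rating for subject {subject}",
                )
            )
    counts = schedule.category_counts
    for cat in CATEGORIES:
        want, have = STUDY_CATEGORY_COUNTS[cat], counts[cat]
        if have != want:
            violations.append(
                Violation(
                    "category_count",
                    f"category {cat!r}: expected {want} videos, found {have} "
                    f"(deficit {want - have})",
                )
            )
    return violations
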
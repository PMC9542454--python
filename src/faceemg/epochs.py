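"""Event-locked aggregation: envelope -> per-video means -> condition means.

The aggregation unit is the video: for each subject, channel and video we
take the mean normalized amplitude over the video interval, then average
those per-video means (unweighted) within a condition. Conditions come in
five schemes:

- ``valence_bin``:  videos the subject rated 1-4 (V_negative) vs 6-9
  (V_positive); a rating of 5 is excluded;
- ``arousal_bin``:  likewise for arousal (A_low / A_high);
- ``video_type``:   the predefined stimulus categories (W_negative,
  W_neutral, W_positive);
- ``valence_level`` / ``arousal_level``: one condition per raw rating level
  1-9 (used for the segmented correlations and the V-shape fit).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplitude import Envelope
from .types import RatingRecord, SessionSchedule

__all__ = [
    "per_video_amplitude",
    "bin_rating",
    "condition_means",
    "SCHEMES",
]

logger = logging.getLogger(__name__)

SCHEMES = ("valence_bin", "arousal_bin", "video_type", "valence_level",
           "arousal_level")

#: Condition labels per scheme, in canonical order.
SCHEME_CONDITIONS = {
    "valence_bin": ("V_negative", "V_positive"),
    "arousal_bin": ("A_low", "A_high"),
    "video_type": ("W_negative", "W_neutral", "W_positive"),
    "valence_level": tuple(str(v) for v in range(1, 10)),
    "arousal_level": tuple(str(v) for v in range(1, 10)),
}


def per_video_amplitude(
    env: Envelope, schedule: SessionSchedule
) -> pd.DataFrame:
    """Mean normalized amplitude per video for one channel.

    An envelope sample belongs to a video when its analysis-window start time
    lies in ``[start_s, end_s)``. Returns a tidy frame with columns
    ``subject_id, video_id, channel, mean_amp``.
    """
    t = env.times()
    span = t[-1]
    rows = []
    for ev in schedule.events:
        if ev.start_s > span:
            raise ValueError(
                f"event {ev.video_id} starts at {ev.start_s:.1f} s, beyond the "
                f"envelope span ({span:.1f} s)"
            )
        mask = (t >= ev.start_s) & (t < ev.end_s)
        if not mask.any():
            raise ValueError(
                f"event {ev.video_id} contains no envelope samples"
            )
        rows.append(
            {
                "subject_id": env.subject_id,
                "video_id": ev.video_id,
                "channel": env.channel,
                "mean_amp": float(env.values[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def bin_rating(rating: int, kind: str) -> str | None:
    """Map a 1-9 rating to its condition bin; the midpoint 5 is excluded.

    Ratings 1-4 are the negative/low bin, 6-9 the positive/high bin.
    """
    if kind not in ("valence", "arousal"):
        raise ValueError(f"kind must be 'valence' or 'arousal', got {kind!r}")
    if not 1 <= rating <= 9:
        raise ValueError(f"rating must be in 1..9, got {rating}")
    if rating == 5:
        return None
    low = rating <= 4
    if kind == "valence":
        return "V_negative" if low else "V_positive"
    return "A_low" if low else "A_high"


def _video_condition(
    video_id: str,
    subject_id: str,
    scheme: str,
    schedule: SessionSchedule,
    rating_map: dict[tuple[str, str], RatingRecord],
) -> str | None:
    if scheme == "video_type":
        return f"W_{schedule.category_of(video_id)}"
    try:
        rating = rating_map[(subject_id, video_id)]
    except KeyError:
        raise ValueError(
            f"no rating for subject {subject_id}, video {video_id} "
            f"(required by scheme {scheme!r})"
        ) from None
    if scheme == "valence_bin":
        return bin_rating(rating.valence, "valence")
    if scheme == "arousal_bin":
        return bin_rating(rating.arousal, "arousal")
    if scheme == "valence_level":
        return str(rating.valence)
    if scheme == "arousal_level":
        return str(rating.arousal)
    raise ValueError(f"unknown scheme {scheme!r}; valid: {list(SCHEMES)}")


def condition_means(
    per_video: pd.DataFrame,
    ratings: Iterable[RatingRecord],
    schedule: SessionSchedule,
    scheme: str,
) -> pd.DataFrame:
    """Per-subject mean normalized amplitude per condition.

    The value is the unweighted mean of the subject's per-video means over
    the videos falling in the condition. Subjects with no video in a
    condition yield no record for it (logged); downstream paired tests drop
    such subjects pairwise.

    Returns a tidy frame with columns
    ``subject_id, channel, scheme, condition, value, n_videos``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {list(SCHEMES)}")
    rating_map = {(r.subject_id, r.video_id): r for r in ratings}
    df = per_video.copy()
    df["condition"] = [
        _video_condition(v, s, scheme, schedule, rating_map)
        for v, s in zip(df["video_id"], df["subject_id"])
    ]
    df = df[df["condition"].notna()]
    if df.empty:
        logger.info("scheme %s: no videos fall in any condition", scheme)
        return pd.DataFrame(
            columns=["subject_id", "channel", "scheme", "condition", "value",
                     "n_videos"]
        )
    grouped = (
        df.groupby(["subject_id", "channel", "condition"], sort=False)["mean_amp"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "value", "size": "n_videos"})
    )
    grouped.insert(2, "scheme", scheme)
    expected = SCHEME_CONDITIONS[scheme]
    if scheme in ("valence_bin", "arousal_bin", "video_type"):
        for sid in grouped["subject_id"].unique():
            have = set(grouped.loc[grouped["subject_id"] == sid, "condition"])
            missing = [c for c in expected if c not in have]
            if missing:
                logger.info(
                    "subject %s has no videos in condition(s) %s under scheme %s",
                    sid, missing, scheme,
                )
    order = {c: i for i, c in enumerate(expected)}
    grouped = grouped.sort_values(
        ["subject_id", "channel", "condition"],
        key=lambda col: col.map(order) if col.name == "condition" else col,
        kind="stable",
    ).reset_index(drop=True)
    return grouped
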
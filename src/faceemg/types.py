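"""Core domain types for facial sEMG sessions.

A *session* is one subject watching an ordered sequence of short affective
videos while five facial sEMG channels are recorded: left/right orbicularis
oculi and left/right zygomaticus major (the "positive" smiling muscles) and
the corrugator supercilii (the "negative" frowning muscle). After each video
the subject self-rates valence and arousal on a 1-9 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical channel order, left-to-right across the face.
CHANNELS: tuple[str, ...] = (
    "l_orbicularis",
    "l_zygomaticus",
    "corrugator",
    "r_zygomaticus",
    "r_orbicularis",
)

#: Muscles associated with positive expressions (smiling).
POSITIVE_MUSCLES: tuple[str, ...] = (
    "l_orbicularis",
    "l_zygomaticus",
    "r_zygomaticus",
    "r_orbicularis",
)

#: Label of the pointwise mean of the five normalized channels.
SENSORS_AVERAGE = "sensors_average"

CATEGORIES: tuple[str, ...] = ("neutral", "negative", "positive")

#: Video-category multiset of a study-conformant 25-video session.
STUDY_CATEGORY_COUNTS = {"neutral": 10, "negative": 6, "positive": 9}

STAGES = ("raw", "denoised", "envelope", "normalized")


class FormatError(ValueError):
    """An on-disk file does not match the documented session format."""


class SessionValidationError(ValueError):
    """A value violates a session-level invariant (range, duplication...)."""


class DegenerateComparisonError(ValueError):
    """A paired comparison has no usable information (all ties / too few pairs)."""


class DegenerateChannelWarning(UserWarning):
    """A channel has zero dynamic range and normalizes to all zeros."""


@dataclass
class EmgRecording:
    """Multichannel sEMG signal for one subject.

    ``samples`` is a ``(n_channels, n_samples)`` float array in sensor units
    (arbitrary voltage units); row order matches ``channels``.
    """

    subject_id: str
    fs: float
    channels: tuple[str, ...]
    samples: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise SessionValidationError(f"fs must be positive, got {self.fs}")
        if self.stage not in STAGES:
            raise SessionValidationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise SessionValidationError(
                "samples must be a (n_channels, n_samples) array matching channels"
            )
        if self.samples.shape[1] < 1:
            raise SessionValidationError("recording must contain at least one sample")
        if len(set(self.channels)) != len(self.channels):
            raise SessionValidationError("channel labels must be unique")
        unknown = [c for c in self.channels if c not in CHANNELS]
        if unknown:
            raise SessionValidationError(
                f"unknown channel labels {unknown}; valid labels: {list(CHANNELS)}"
            )
        if self.stage == "normalized":
            lo, hi = float(self.samples.min()), float(self.samples.max())
            if lo < -1e-12 or hi > 1 + 1e-12:
                raise SessionValidationError(
                    f"stage=normalized requires values in [0, 1], got [{lo}, {hi}]"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording; have {list(self.channels)}"
            ) from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray, stage: str) -> "EmgRecording":
        return EmgRecording(
            subject_id=self.subject_id,
            fs=self.fs,
            channels=self.channels,
            samples=samples,
            stage=stage,
        )


@dataclass(frozen=True)
class VideoEvent:
    """One video presentation: half-open interval [start_s, end_s)."""

    video_id: str
    category: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SessionValidationError(
                f"unknown category {self.category!r}; valid: {list(CATEGORIES)}"
            )
        if not self.end_s > self.start_s:
            raise SessionValidationError(
                f"event {self.video_id}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionSchedule:
    """Ordered video events with rating breaks between them.

    Times are seconds from session start (0-based). Consecutive events are
    separated by at least ``break_s`` (the rating break).
    """

    subject_id: str
    events: list[VideoEvent]
    break_s: float = 10.0

    def __post_init__(self) -> None:
        self.events = list(self.events)
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.start_s - prev.end_s < self.break_s - 1e-9:
                raise SessionValidationError(
                    f"events {prev.video_id} and {nxt.video_id} are separated by "
                    f"{nxt.start_s - prev.end_s:.3f} s < break_s={self.break_s} s"
                )

    @property
    def span_s(self) -> float:
        """Session length: end of the last video plus its rating break."""
        return self.events[-1].end_s + self.break_s

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for ev in self.events:
            counts[ev.category] += 1
        return counts

    def category_of(self, video_id: str) -> str:
        for ev in self.events:
            if ev.video_id == video_id:
                return ev.category
        raise KeyError(f"video {video_id!r} not in schedule")

    def for_subject(self, subject_id: str) -> "SessionSchedule":
        return SessionSchedule(subject_id, list(self.events), self.break_s)


@dataclass(frozen=True)
class RatingRecord:
    """Self-reported valence and arousal (1-9 integers) for one video."""

    subject_id: str
    video_id: str
    valence: int
    arousal: int

    def __post_init__(self) -> None:
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 9):
                raise SessionValidationError(
                    f"{name} must be an integer in 1..9, got {v!r} "
                    f"(subject {self.subject_id}, video {self.video_id})"
                )


def check_unique_ratings(records: Iterable[RatingRecord]) -> None:
    """Raise if any (subject, video) pair is rated more than once."""
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.subject_id, r.video_id)
        if key in seen:
            raise SessionValidationError(
                f"duplicate rating for subject {r.subject_id}, video {r.video_id}"
            )
        seen.add(key)
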
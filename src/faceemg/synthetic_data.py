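"""Synthetic facial-sEMG cohorts with the statistical structure the analysis assumes.

Each simulated channel is band-limited Gaussian carrier noise whose running
standard deviation is modulated per video: a muscle- and category-specific
activation gain, optionally coupled to the subject's arousal rating for the
video. On top of the myogenic carrier the generator adds 50 Hz powerline
interference with harmonics and sub-20 Hz motion/blink artifacts, so the
denoising stage has realistic work to do. Self-report ratings are drawn per
video category from a discretized truncated normal whose per-category
means/SDs default to the study's manipulation-check table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from . import io_core
from .types import (
    CATEGORIES,
    CHANNELS,
    EmgRecording,
    RatingRecord,
    SessionSchedule,
    SessionValidationError,
    VideoEvent,
)

__all__ = [
    "EffectProfile",
    "CohortConfig",
    "Cohort",
    "default_study_schedule",
    "simulate_session",
    "simulate_cohort",
]

#: Per-category (mean, SD) of valence and arousal self-reports, matching the
#: study's manipulation check: the negative videos are unpleasant and
#: arousing, the positive ones pleasant and arousing, the neutral ones
#: mid-valence and calm.
STUDY_RATING_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "neutral": {"valence": (4.65, 1.11), "arousal": (3.41, 1.65)},
    "negative": {"valence": (3.18, 1.70), "arousal": (6.67, 1.40)},
    "positive": {"valence": (6.60, 1.26), "arousal": (5.88, 1.48)},
}

#: Session layout: four blocks of (category, n_videos, total block seconds).
STUDY_BLOCKS: tuple[tuple[str, int, float], ...] = (
    ("neutral", 5, 76.0),
    ("negative", 6, 93.0),
    ("neutral", 5, 81.0),
    ("positive", 9, 78.0),
)


def _default_gains() -> dict[str, dict[str, float]]:
    # Positive muscles activate most for positive content, somewhat for
    # negative (arousing) content, least for neutral; the corrugator frowns
    # hardest at negative content and relaxes for positive content.
    positive = {"rest": 0.7, "neutral": 1.0, "negative": 1.25, "positive": 1.9}
    corrugator = {"rest": 0.7, "neutral": 1.3, "negative": 1.5, "positive": 1.05}
    return {
        ch: dict(corrugator if ch == "corrugator" else positive) for ch in CHANNELS
    }


def _default_coupling() -> dict[str, float]:
    # The corrugator shows no arousal dependence; the smiling muscles scale
    # with subjective arousal.
    return {ch: (0.0 if ch == "corrugator" else 0.4) for ch in CHANNELS}


@dataclass
class EffectProfile:
    """Ground-truth effect structure of a simulated cohort.

    ``gain[muscle][category]`` multiplies the carrier SD during videos of
    that category ("rest" applies during rating breaks).
    ``arousal_coupling[muscle]`` scales the envelope by
    ``1 + coupling * (arousal - 5) / 4``, so a unit coupling doubles the
    envelope at arousal 9 and zeroes the modulation at the scale midpoint.
    """

    gain: dict[str, dict[str, float]] = field(default_factory=_default_gains)
    arousal_coupling: dict[str, float] = field(default_factory=_default_coupling)
    rating_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            c: {s: STUDY_RATING_MODEL[c][s] for s in ("valence", "arousal")}
            for c in CATEGORIES
        }
    )

    def __post_init__(self) -> None:
        for ch, per_cat in self.gain.items():
            for cat, g in per_cat.items():
                if g < 0:
                    raise SessionValidationError(
                        f"gain[{ch}][{cat}] must be >= 0, got {g}"
                    )

    @classmethod
    def null(cls) -> "EffectProfile":
        """No muscle-condition dependence: equal gains, zero coupling.

        Ratings keep the default per-category model so rating-based binning
        still produces populated conditions.
        """
        gains = {
            ch: {"rest": 0.7, "neutral": 1.0, "negative": 1.0, "positive": 1.0}
            for ch in CHANNELS
        }
        coupling = {ch: 0.0 for ch in CHANNELS}
        return cls(gain=gains, arousal_coupling=coupling)


@dataclass
class CohortConfig:
    """Everything needed to regenerate a cohort deterministically."""

    n_subjects: int = 38
    fs: float = 1000.0
    seed: int = 0
    effect: EffectProfile = field(default_factory=EffectProfile)
    powerline_amplitude: float = 1.0  # 50 Hz amplitude, x baseline carrier SD
    powerline_harmonics: int = 3  # 50, 100, 150 Hz
    artifact_level: float = 2.0  # sub-20 Hz drift/blink SD, x baseline SD
    emg_band: tuple[float, float] = (20.0, 450.0)
    baseline_sd: float = 10.0  # carrier SD in sensor units at unit gain
    break_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SessionValidationError("n_subjects must be >= 1")
        lo, hi = self.emg_band
        if not (0 < lo < hi):
            raise SessionValidationError(f"invalid emg_band {self.emg_band}")
        if hi >= self.fs / 2:
            raise SessionValidationError(
                f"emg_band upper edge {hi} Hz must be below Nyquist "
                f"({self.fs / 2} Hz)"
            )


def default_study_schedule(
    subject_id: str = "template", break_s: float = 10.0
) -> SessionSchedule:
    """The fixed 25-video session: 5 neutral (76 s), 6 negative (93 s),
    5 neutral (81 s), 9 positive (78 s), with rating breaks in between.

    Each block's total duration is split evenly across its videos.
    """
    events: list[VideoEvent] = []
    t = 0.0
    idx = 1
    for category, n, block_s in STUDY_BLOCKS:
        dur = block_s / n
        for _ in range(n):
            events.append(
                VideoEvent(
                    video_id=f"v{idx:02d}",
                    category=category,
                    start_s=t,
                    end_s=t + dur,
                )
            )
            t += dur + break_s
            idx += 1
    return SessionSchedule(subject_id=subject_id, events=events, break_s=break_s)


def _draw_ratings(
    schedule: SessionSchedule,
    profile: EffectProfile,
    rng: np.random.Generator,
    subject_id: str,
) -> list[RatingRecord]:
    records = []
    for ev in schedule.events:
        model = profile.rating_model[ev.category]
        vals = {}
        for scale in ("valence", "arousal"):
            mean, sd = model[scale]
            vals[scale] = int(np.clip(np.rint(rng.normal(mean, sd)), 1, 9))
        records.append(
            RatingRecord(
                subject_id=subject_id,
                video_id=ev.video_id,
                valence=vals["valence"],
                arousal=vals["arousal"],
            )
        )
    return records


def _gain_profile(
    schedule: SessionSchedule,
    channel: str,
    profile: EffectProfile,
    ratings_by_video: dict[str, RatingRecord],
    fs: float,
    n: int,
) -> np.ndarray:
    """Per-sample carrier-SD multiplier: piecewise per video with 100 ms
    raised-cosine transitions (avoids spectral edge ringing)."""
    gains = profile.gain[channel]
    coupling = profile.arousal_coupling.get(channel, 0.0)
    g = np.full(n, gains["rest"], dtype=float)
    for ev in schedule.events:
        i0 = int(round(ev.start_s * fs))
        i1 = min(int(round(ev.end_s * fs)), n)
        level = gains[ev.category]
        if coupling:
            arousal = ratings_by_video[ev.video_id].arousal
            level *= max(0.0, 1.0 + coupling * (arousal - 5) / 4.0)
        g[i0:i1] = level
    ramp = max(3, int(round(0.1 * fs)))
    win = np.hanning(ramp)
    win /= win.sum()
    return sps.fftconvolve(g, win, mode="same")


def _bandlimited_carrier(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std()


def _artifacts(
    rng: np.random.Generator, n: int, fs: float, level: float
) -> np.ndarray:
    """Sub-20 Hz nuisance: slow random-walk drift plus blink-like pulses."""
    if level <= 0:
        return np.zeros(n)
    # 0.3 Hz random-walk drift
    sos = sps.butter(2, 0.3, btype="lowpass", fs=fs, output="sos")
    drift = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = drift.std()
    drift = drift / sd * level if sd > 0 else drift
    # Poisson-timed 200 ms biphasic blink pulses (~5 Hz content)
    pulse_len = max(4, int(round(0.2 * fs)))
    tt = np.arange(pulse_len) / pulse_len
    pulse = np.sin(2 * np.pi * tt) * np.hanning(pulse_len)
    out = drift.copy()
    n_blinks = rng.poisson(0.2 * n / fs)
    if n_blinks:
        starts = rng.integers(0, max(1, n - pulse_len), size=n_blinks)
        amp = 3.0 * level
        for s in starts:
            out[s : s + pulse_len] += amp * pulse
    return out


def _powerline(
    rng: np.random.Generator,
    n: int,
    fs: float,
    amplitude: float,
    n_harmonics: int,
    base_hz: float = 50.0,
) -> np.ndarray:
    if amplitude <= 0 or n_harmonics < 1:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        f = k * base_hz
        if f >= fs / 2:
            break
        phase = rng.uniform(0, 2 * np.pi)
        out += amplitude / k * np.sin(2 * np.pi * f * t + phase)
    return out


def simulate_session(
    schedule: SessionSchedule,
    config: CohortConfig,
    subject_seed: int,
    subject_id: str | None = None,
) -> tuple[EmgRecording, list[RatingRecord]]:
    """Simulate one subject's raw recording and ratings.

    The output is a pure function of ``(schedule, config, subject_seed)``:
    the same inputs reproduce the session bit for bit.
    """
    if subject_id is None:
        subject_id = schedule.subject_id
    rng = np.random.default_rng(subject_seed)
    fs = config.fs
    n = int(round(schedule.span_s * fs))
    ratings = _draw_ratings(schedule, config.effect, rng, subject_id)
    by_video = {r.video_id: r for r in ratings}
    rows = []
    for ch in CHANNELS:
        carrier = _bandlimited_carrier(rng, n, fs, config.emg_band)
        g = _gain_profile(schedule, ch, config.effect, by_video, fs, n)
        x = config.baseline_sd * g * carrier
        x += config.baseline_sd * _powerline(
            rng, n, fs, config.powerline_amplitude, config.powerline_harmonics
        )
        x += config.baseline_sd * _artifacts(rng, n, fs, config.artifact_level)
        rows.append(x)
    recording = EmgRecording(
        subject_id=subject_id,
        fs=fs,
        channels=CHANNELS,
        samples=np.vstack(rows),
        stage="raw",
    )
    return recording, ratings


def subject_seeds(config: CohortConfig) -> np.ndarray:
    """Deterministic per-subject seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(config.n_subjects, dtype=np.uint32) & 0x7FFFFFFF


@dataclass
class Cohort:
    """A simulated cohort; recordings are regenerated lazily per subject so a
    full-size cohort never has to sit in memory at once."""

    config: CohortConfig
    schedule: SessionSchedule

    @property
    def subject_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.config.n_subjects)]

    def iter_sessions(
        self,
    ) -> Iterator[tuple[EmgRecording, SessionSchedule, list[RatingRecord]]]:
        seeds = subject_seeds(self.config)
        for sid, seed in zip(self.subject_ids, seeds):
            sched = self.schedule.for_subject(sid)
            rec, ratings = simulate_session(sched, self.config, int(seed), sid)
            yield rec, sched, ratings

    def all_ratings(self) -> list[RatingRecord]:
        out: list[RatingRecord] = []
        seeds = subject_seeds(self.config)
        for sid, seed in zip(self.subject_ids, seeds):
            sched = self.schedule.for_subject(sid)
            rng = np.random.default_rng(int(seed))
            out.extend(_draw_ratings(sched, self.config.effect, rng, sid))
        return out

    def schedules(self) -> list[SessionSchedule]:
        return [self.schedule.for_subject(sid) for sid in self.subject_ids]


def simulate_cohort(
    config: CohortConfig,
    schedule: SessionSchedule | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Build a cohort; optionally write it to ``out_dir`` in the session format.

    Rating draws happen before the per-channel signal draws within each
    subject's RNG stream, so ``Cohort.all_ratings`` reproduces exactly the
    ratings embedded in the written sessions without generating the signals.
    """
    if schedule is None:
        schedule = default_study_schedule(break_s=config.break_s)
    cohort = Cohort(config=config, schedule=schedule)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        all_ratings: list[RatingRecord] = []
        for rec, sched, ratings in cohort.iter_sessions():
            io_core.write_recording(rec, out_dir / f"{rec.subject_id}_raw.csv")
            all_ratings.extend(ratings)
        io_core.write_schedule(cohort.schedules(), out_dir / "schedule.csv")
        io_core.write_ratings(all_ratings, out_dir / "ratings.csv")
    return cohort
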
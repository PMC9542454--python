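"""Normalized amplitude envelopes.

The denoised sEMG is reduced to a slowly-varying amplitude measure: sliding
root-mean-square (or mean-absolute-value) windows, winsorized per subject and
channel at the 5th/95th percentiles (below-p5 values are zeroed, above-p95
values clipped to p95), then min-max normalized to [0, 1] per subject. The
five normalized channels can finally be averaged pointwise into a
"sensors_average" trace.

Because winsorization and min-max normalization are scale-equivariant and the
RMS is positively homogeneous, the normalized envelope is invariant to any
positive rescaling of the raw channel — sensor units never matter downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import design_filters  # noqa: F401  (re-exported pipeline aid)
from .types import CHANNELS, SENSORS_AVERAGE, DegenerateChannelWarning, EmgRecording

__all__ = [
    "Envelope",
    "amplitude_envelope",
    "winsorize_envelope",
    "normalize_envelope",
    "sensor_average",
    "normalized_envelopes",
]

DEFAULT_WINDOW_S = 0.25
DEFAULT_HOP_S = 0.05


@dataclass
class Envelope:
    """Nonnegative amplitude trace sampled at ``fs_env`` Hz.

    Sample ``i`` summarizes the analysis window starting at ``i / fs_env``
    seconds; ``times()`` returns those window-start times.
    """

    subject_id: str
    channel: str
    fs_env: float
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("envelope values must be a non-empty 1-D array")
        if np.any(self.values < -1e-12):
            raise ValueError("envelope values must be nonnegative")
        if self.normalized and self.values.max() > 1 + 1e-12:
            raise ValueError("normalized envelope must lie in [0, 1]")

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs_env


def amplitude_envelope(
    signal: np.ndarray,
    fs: float,
    subject_id: str = "",
    channel: str = "",
    method: str = "rms",
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
) -> Envelope:
    """Sliding-window RMS or MAV amplitude.

    Window ``i`` covers samples ``[i*hop, i*hop + wlen)``; the envelope has
    ``floor((N - wlen) / hop) + 1`` samples at rate ``fs / hop``.
    """
    signal = np.asarray(signal, dtype=float)
    if not (0 < hop_s <= window_s):
        raise ValueError(f"need 0 < hop_s ({hop_s}) <= window_s ({window_s})")
    wlen = int(round(window_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    if wlen < 2:
        raise ValueError(f"window of {wlen} samples is too short (need >= 2)")
    if wlen > signal.size:
        raise ValueError(
            f"window of {wlen} samples exceeds signal length {signal.size}"
        )
    windows = sliding_window_view(signal, wlen)[::hop]
    if method == "rms":
        values = np.sqrt(np.mean(windows**2, axis=1))
    elif method == "mav":
        values = np.mean(np.abs(windows), axis=1)
    else:
        raise ValueError(f"unknown method {method!r}; use 'rms' or 'mav'")
    return Envelope(
        subject_id=subject_id, channel=channel, fs_env=fs / hop, values=values
    )


def winsorize_envelope(
    env: Envelope, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> Envelope:
    """Asymmetric winsorization over the whole envelope: values strictly below
    the ``lo_pct`` percentile are set to 0 (suppressing incidental baseline
    activity), values strictly above the ``hi_pct`` percentile are clipped to
    it (suppressing amplitude bursts)."""
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError(f"need 0 <= lo_pct < hi_pct <= 100, got {lo_pct}, {hi_pct}")
    p_lo, p_hi = np.percentile(env.values, [lo_pct, hi_pct])
    values = env.values.copy()
    values[values < p_lo] = 0.0
    values[values > p_hi] = p_hi
    return replace(env, values=values)


def normalize_envelope(env: Envelope) -> Envelope:
    """Person-specific min-max normalization to [0, 1].

    A zero-dynamic-range channel maps to all zeros and emits a
    :class:`DegenerateChannelWarning`.
    """
    lo = env.values.min()
    hi = env.values.max()
    if hi - lo <= 0:
        warnings.warn(
            f"channel {env.channel!r} of subject {env.subject_id!r} has zero "
            "dynamic range; normalized to all zeros",
            DegenerateChannelWarning,
            stacklevel=2,
        )
        values = np.zeros_like(env.values)
    else:
        values = (env.values - lo) / (hi - lo)
    return replace(env, values=values, normalized=True)


def sensor_average(envelopes: list[Envelope]) -> Envelope:
    """Pointwise mean of the five normalized channel envelopes."""
    labels = sorted(e.channel for e in envelopes)
    if labels != sorted(CHANNELS):
        raise ValueError(
            f"sensor_average needs exactly the channels {list(CHANNELS)}, "
            f"got {labels}"
        )
    lengths = {e.values.size for e in envelopes}
    if len(lengths) != 1:
        raise ValueError(f"envelope lengths differ: {sorted(lengths)}")
    if not all(e.normalized for e in envelopes):
        raise ValueError("sensor_average requires normalized envelopes")
    stacked = np.vstack([e.values for e in envelopes])
    ref = envelopes[0]
    return Envelope(
        subject_id=ref.subject_id,
        channel=SENSORS_AVERAGE,
        fs_env=ref.fs_env,
        values=stacked.mean(axis=0),
        normalized=True,
    )


def normalized_envelopes(
    recording: EmgRecording,
    method: str = "rms",
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> dict[str, Envelope]:
    """Full amplitude stage for a denoised recording.

    Returns one normalized envelope per channel plus their
    ``sensors_average``. Winsorization and normalization run per channel over
    the whole session (rating breaks included).
    """
    if recording.stage != "denoised":
        raise ValueError(
            f"expected a denoised recording, got stage={recording.stage!r}"
        )
    per_channel: dict[str, Envelope] = {}
    for ch in recording.channels:
        env = amplitude_envelope(
            recording.channel(ch),
            recording.fs,
            subject_id=recording.subject_id,
            channel=ch,
            method=method,
            window_s=window_s,
            hop_s=hop_s,
        )
        env = winsorize_envelope(env, lo_pct, hi_pct)
        per_channel[ch] = normalize_envelope(env)
    per_channel[SENSORS_AVERAGE] = sensor_average(list(per_channel.values()))
    return per_channel
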
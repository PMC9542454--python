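import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from faceemg.synthetic_data import CohortConfig, EffectProfile
from faceemg.types import SessionSchedule, VideoEvent

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_short_schedule(
    subject_id: str = "s01",
    videos_per_category: int = 2,
    video_s: float = 6.0,
    break_s: float = 10.0,
) -> SessionSchedule:
    """A reduced session: blocks of neutral/negative/positive videos."""
    events = []
    t = 0.0
    idx = 1
    for cat in ("neutral", "negative", "positive"):
        for _ in range(videos_per_category):
            events.append(
                VideoEvent(f"v{idx:02d}", cat, t, t + video_s)
            )
            t += video_s + break_s
            idx += 1
    return SessionSchedule(subject_id, events, break_s)


@pytest.fixture
def short_schedule() -> SessionSchedule:
    return make_short_schedule()


@pytest.fixture
def small_config() -> CohortConfig:
    """A cheap-to-simulate cohort configuration for unit tests."""
    return CohortConfig(
        n_subjects=2,
        fs=500.0,
        seed=11,
        emg_band=(20.0, 220.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
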
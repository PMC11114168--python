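import numpy as np
import pytest

from vaeeg.core import Event, EventSchedule, MONTAGE_16, Recording
from vaeeg.synth import SynthConfig, generate_session

TREATMENTS = ["MA1", "MA2", "VA1", "VA2", "VA3", "VA4"]


def six_event_schedule(event_seconds: float = 300.0) -> EventSchedule:
    """All six treatment events back to back on one day (no rests),
    used by simulation studies where only treatment segments matter."""
    return EventSchedule([
        Event(name, 1, i * event_seconds, event_seconds)
        for i, name in enumerate(TREATMENTS)
    ])


@pytest.fixture
def short_schedule() -> EventSchedule:
    return six_event_schedule(20.0)


@pytest.fixture
def small_recording() -> Recording:
    rng = np.random.default_rng(42)
    return Recording(rng.normal(0.0, 30.0, (16, 1000)), 125.0, MONTAGE_16,
                     [("MA1", 1.0, 4.0), ("rest", 5.0, 2.5)])


@pytest.fixture
def blinky_session() -> tuple[Recording, Recording, list[float], SynthConfig]:
    """(clean, with-blinks, truth onsets, config) for a 3-minute session."""
    from vaeeg.synth import inject_blinks

    schedule = EventSchedule([Event("MA1", 1, 0.0, 120.0),
                              Event("rest", 1, 120.0, 60.0)])
    config = SynthConfig(seed=7)
    clean = generate_session(config, schedule)
    blinky, truth = inject_blinks(clean, config)
    return clean, blinky, truth, config
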
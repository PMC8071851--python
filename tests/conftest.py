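import numpy as np
import pytest

from breathsync import OnsetEvent, OnsetKind


def periodic_events(
    period: float = 6.0,
    ratio: float = 2.0,
    duration: float = 480.0,
    start: float = 1.0,
) -> list[OnsetEvent]:
    """Perfectly periodic alternating onsets with exhale/inhale = ratio."""
    inhale = period / (1.0 + ratio)
    events = []
    t = start
    while t < duration:
        events.append(OnsetEvent(t, OnsetKind.INHALE))
        if t + inhale >= duration:
            break
        events.append(OnsetEvent(t + inhale, OnsetKind.EXHALE))
        t += period
    return events


@pytest.fixture
def clean_trial():
    """Clean 480 s trial: 6 s cycles (10 breaths/min), 2 s in / 4 s out."""
    return periodic_events(period=6.0, ratio=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
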
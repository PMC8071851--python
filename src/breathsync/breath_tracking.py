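"""Breathing phase and tempo tracking from inhale/exhale onset events.

The tracked breather is modeled as a wrapped phase in degrees that is
snapped to a fixed angle at every accepted keypress onset -- 0° at an
inhale onset, ``exhale_phase`` (default 240°) at an exhale onset -- and
advances linearly at the current breathing tempo between onsets.  Tempo
is estimated from the recent inter-onset-interval (IOI) history: the
classic estimate is the median of the last five IOIs; the full-cycle
period preferred here is the median of recent inhale-to-inhale
intervals, which is independent of the inhale:exhale ratio.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, replace


class OnsetKind(enum.Enum):
    """Which half of the breath cycle a keypress marks."""

    INHALE = "inhale"
    EXHALE = "exhale"


class IngestResult(enum.Enum):
    """Outcome of feeding one onset event to the tracker."""

    ACCEPTED = "accepted"
    REJECTED_DEBOUNCE = "rejected_debounce"
    REJECTED_NON_MONOTONE = "rejected_non_monotone"


@dataclass(frozen=True)
class OnsetEvent:
    """One timestamped inhale or exhale keypress.

    Parameters
    ----------
    time : float
        Seconds from trial start; must be non-negative.
    kind : OnsetKind
        Inhale or exhale.
    """

    time: float
    kind: OnsetKind

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"onset time must be >= 0, got {self.time}")
        if not isinstance(self.kind, OnsetKind):
            object.__setattr__(self, "kind", OnsetKind(self.kind))


@dataclass(frozen=True)
class TrackerConfig:
    """Conventions and guards of the phase tracker.

    ``exhale_phase`` is the angle the phase snaps to at an exhale onset;
    240° follows the original system's convention (see the module's
    continuity dichotomy: a 1:2 inhale:exhale breather free-runs to 120°
    by the exhale onset, so 240° introduces a deliberate jump).
    ``default_period`` (5 s, i.e. 12 breaths/min) is used before enough
    onsets exist.  ``debounce`` suppresses keyboard double-fires.
    """

    exhale_phase: float = 240.0
    ioi_window: int = 5
    default_period: float = 5.0
    debounce: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.exhale_phase < 360.0:
            raise ValueError("exhale_phase must lie strictly inside (0, 360)")
        if self.ioi_window < 1:
            raise ValueError("ioi_window must be >= 1")
        if self.default_period <= 0:
            raise ValueError("default_period must be positive")
        if self.debounce < 0:
            raise ValueError("debounce must be >= 0")


@dataclass(frozen=True)
class BreathState:
    """Immutable tracker state after some number of accepted onsets.

    ``ioi_history`` holds mixed half-cycle intervals (inhale→exhale and
    exhale→inhale alike); ``full_cycle_history`` holds inhale-to-inhale
    intervals only.  ``period`` is the current full-cycle estimate.
    """

    period: float
    phase_at_last_onset: float = 0.0
    last_onset: OnsetEvent | None = None
    last_inhale_time: float | None = None
    ioi_history: tuple[float, ...] = ()
    full_cycle_history: tuple[float, ...] = ()

    @property
    def has_onset(self) -> bool:
        return self.last_onset is not None


def new_state(cfg: TrackerConfig | None = None) -> BreathState:
    """Fresh tracker state with the configured default period."""
    cfg = cfg or TrackerConfig()
    return BreathState(period=cfg.default_period)


def ingest_onset(
    state: BreathState, cfg: TrackerConfig, event: OnsetEvent
) -> tuple[BreathState, IngestResult]:
    """Feed one keypress onset to the tracker.

    On acceptance the phase snaps to 0° (inhale) or ``cfg.exhale_phase``
    (exhale), the interval to the previous accepted onset is appended to
    the IOI history, and the period re-estimated.  Events within
    ``cfg.debounce`` seconds of the previous accepted event are rejected
    without state change; a timestamp at or before the previous accepted
    one is rejected with a distinct non-monotone signal.

    Returns
    -------
    (BreathState, IngestResult)
        The (possibly unchanged) state and the outcome.
    """
    if state.last_onset is not None:
        dt = event.time - state.last_onset.time
        if dt <= 0:
            return state, IngestResult.REJECTED_NON_MONOTONE
        if dt < cfg.debounce:
            return state, IngestResult.REJECTED_DEBOUNCE
        ioi_history = (state.ioi_history + (dt,))[-cfg.ioi_window :]
    else:
        ioi_history = state.ioi_history

    full_history = state.full_cycle_history
    last_inhale = state.last_inhale_time
    if event.kind is OnsetKind.INHALE:
        if last_inhale is not None:
            full_history = (full_history + (event.time - last_inhale,))[
                -cfg.ioi_window :
            ]
        last_inhale = event.time

    snapped = 0.0 if event.kind is OnsetKind.INHALE else cfg.exhale_phase
    new = replace(
        state,
        phase_at_last_onset=snapped,
        last_onset=event,
        last_inhale_time=last_inhale,
        ioi_history=ioi_history,
        full_cycle_history=full_history,
    )
    new = replace(new, period=estimate_period(new, cfg))
    return new, IngestResult.ACCEPTED


def median_ioi(state: BreathState, cfg: TrackerConfig) -> float | None:
    """Median of the most recent ``cfg.ioi_window`` mixed IOIs, or None.

    This is the raw tempo statistic of the original system (median of
    the last five inter-onset intervals); it mixes inhale→exhale and
    exhale→inhale half-cycle intervals.
    """
    if not state.ioi_history:
        return None
    return statistics.median(state.ioi_history[-cfg.ioi_window :])


def estimate_period(state: BreathState, cfg: TrackerConfig) -> float:
    """Current full-breath-cycle period in seconds.

    Prefers the median of recent inhale-to-inhale intervals (ratio
    independent); falls back to twice the mixed half-cycle IOI median
    early in a trial, and to ``cfg.default_period`` before any interval
    exists.  Deterministic.
    """
    if state.full_cycle_history:
        return statistics.median(state.full_cycle_history[-cfg.ioi_window :])
    m = median_ioi(state, cfg)
    if m is not None:
        return 2.0 * m
    return cfg.default_period


def phase_at(state: BreathState, cfg: TrackerConfig, t: float) -> float:
    """Breathing phase in degrees at time ``t``.

    Linear interpolation at the current tempo from the phase snapped at
    the last accepted onset; free-runs and wraps past 360° (no
    lookahead toward the next snap target).  ``t`` must not precede the
    last accepted onset.
    """
    if state.last_onset is None:
        # No onset yet: phase free-runs from 0 at the default tempo.
        anchor_t, anchor_phase = 0.0, 0.0
    else:
        anchor_t, anchor_phase = state.last_onset.time, state.phase_at_last_onset
    if t < anchor_t:
        raise ValueError(
            f"query time {t} precedes last accepted onset at {anchor_t}"
        )
    return (anchor_phase + 360.0 * (t - anchor_t) / state.period) % 360.0


def track_events(
    events: list[OnsetEvent], cfg: TrackerConfig | None = None
) -> tuple[BreathState, list[IngestResult]]:
    """Run the tracker over a full event list; convenience wrapper."""
    cfg = cfg or TrackerConfig()
    state = new_state(cfg)
    results = []
    for ev in events:
        state, res = ingest_onset(state, cfg, ev)
        results.append(res)
    return state, results
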
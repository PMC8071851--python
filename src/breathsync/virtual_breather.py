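"""A simulated participant that closes the biofeedback loop.

The virtual breather emits inhale/exhale onsets from an onset-level
update: each next onset is the intrinsic continuation (from its
breathing rate and exhale:inhale ratio) pulled toward the stimulus
oscillator's corresponding phase landmark with weight ``entrain_gain``,
plus truncated Gaussian timing jitter.  Its ratio drifts toward the
stimulus's implied ratio with ``ratio_gain`` per cycle.  Running the
breather against the scheduler, phase tracker and Kuramoto stimulus
yields a fully deterministic session log -- a drop-in replacement for a
participant's keypress file -- without any human data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breath_tracking import (
    BreathState,
    OnsetEvent,
    OnsetKind,
    TrackerConfig,
    ingest_onset,
    new_state,
    phase_at,
)
from .entrainment import (
    CouplingConfig,
    Oscillator,
    SyncWindow,
    kuramoto_step,
    target_offset,
)
from .scheduler import AlignmentMode, SessionSchedule, build_schedule


@dataclass(frozen=True)
class BreatherParams:
    """Virtual participant parameters.

    intrinsic_rate : breaths per minute (default 8, a relaxed but
        not-yet-slow breather; the biofeedback goal is ~6).
    intrinsic_ratio : exhale/inhale duration (default 1.5; the goal
        state is the healthier 2.0).
    jitter_sd : onset timing jitter SD in seconds, truncated at 3 SD.
    entrain_gain : 0 (deaf to the stimulus) .. 1 (locks to it).
    ratio_gain : per-cycle drift of the ratio toward the stimulus's.
    """

    intrinsic_rate: float = 8.0
    intrinsic_ratio: float = 1.5
    jitter_sd: float = 0.15
    entrain_gain: float = 0.3
    ratio_gain: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intrinsic_rate <= 0 or self.intrinsic_ratio <= 0:
            raise ValueError("rate and ratio must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for g in (self.entrain_gain, self.ratio_gain):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gains must lie in [0, 1]")


@dataclass
class BreatherState:
    """Mutable per-cycle state of the virtual breather."""

    last_time: float
    next_kind: OnsetKind
    ratio: float


@dataclass
class SessionLog:
    """Everything one closed-loop run produced."""

    events: list[OnsetEvent]
    trace: pd.DataFrame
    schedule: SessionSchedule
    params: BreatherParams


def _intrinsic_durations(rate: float, ratio: float) -> tuple[float, float]:
    period = 60.0 / rate
    inhale = period / (1.0 + ratio)
    return inhale, period - inhale


def _landmark(kind: OnsetKind, exhale_landmark: float) -> float:
    return 0.0 if kind is OnsetKind.INHALE else exhale_landmark


def next_onset(
    state: BreatherState,
    params: BreatherParams,
    stim_phase_fn,
    t: float,
    rng: np.random.Generator,
    entrain_active: bool = True,
    exhale_landmark: float = 240.0,
    stim_ratio: float = 2.0,
    scan_dt: float = 0.01,
) -> tuple[OnsetEvent, BreatherState]:
    """Produce the breather's next onset event after time ``t``.

    The intrinsic candidate is ``last_time`` plus the current
    inhale/exhale duration.  When entrainment is active, the stimulus
    candidate is the crossing of the stimulus phase through the
    corresponding alignment cue, in the tracker's phase convention
    (0 deg for the inhale cue, ``exhale_landmark`` = 240 deg for the
    exhale cue, so that in perfect lock the cues coincide with the
    breather's own presses), nearest the intrinsic candidate, found by scanning
    ``stim_phase_fn`` on a ``scan_dt`` grid.  The emitted time is the
    convex blend with weight ``entrain_gain`` plus jitter truncated at
    +/-3 SD; the ratio drifts toward ``stim_ratio``, the exhale:inhale
    ratio the sound is designed for.
    """
    inhale_dur, exhale_dur = _intrinsic_durations(params.intrinsic_rate, state.ratio)
    # Duration of the segment that ENDS at the next onset: the segment
    # now in progress.  If next onset is an exhale, we are inhaling.
    dur = inhale_dur if state.next_kind is OnsetKind.EXHALE else exhale_dur
    t_intr = state.last_time + dur

    t_next = t_intr
    ratio = state.ratio
    if entrain_active and params.entrain_gain > 0.0:
        landmark = _landmark(state.next_kind, exhale_landmark)
        period_guess = 60.0 / params.intrinsic_rate
        lo = max(t, state.last_time + 0.25 * dur)
        hi = t_intr + 0.75 * period_guess
        grid = np.arange(lo, hi, scan_dt)
        if len(grid) >= 2:
            ph = np.asarray([stim_phase_fn(g) for g in grid], dtype=float)
            diff = (ph - landmark + 180.0) % 360.0 - 180.0
            crossings = grid[1:][(diff[:-1] < 0) & (diff[1:] >= 0)]
            if len(crossings):
                t_stim = crossings[np.argmin(np.abs(crossings - t_intr))]
                t_next = t_intr + params.entrain_gain * (t_stim - t_intr)
    if entrain_active and state.next_kind is OnsetKind.INHALE:
        # Ratio drift is its own channel, applied once per closing cycle.
        ratio = ratio + params.ratio_gain * (stim_ratio - ratio)

    if params.jitter_sd > 0.0:
        j = float(rng.normal(0.0, params.jitter_sd))
        j = max(-3.0 * params.jitter_sd, min(3.0 * params.jitter_sd, j))
        t_next += j
    t_next = max(t_next, state.last_time + 0.3)  # physiological floor

    event = OnsetEvent(time=t_next, kind=state.next_kind)
    new_state = BreatherState(
        last_time=t_next,
        next_kind=(
            OnsetKind.EXHALE
            if state.next_kind is OnsetKind.INHALE
            else OnsetKind.INHALE
        ),
        ratio=ratio,
    )
    return event, new_state


def closed_loop_session(
    params: BreatherParams,
    schedule: SessionSchedule | None = None,
    seed: int | None = None,
    tracker_cfg: TrackerConfig | None = None,
    coupling_cfg: CouplingConfig | None = None,
    stim_ratio: float = 2.0,
    trace_stride: int = 10,
) -> SessionLog:
    """Run scheduler + tracker + Kuramoto stimulus + breather together.

    Integrates at ``coupling_cfg.dt`` (default 10 ms) for the whole
    schedule (default 480 s).  The control-rate trace (decimated by
    ``trace_stride``) records time, both phases, stimulus frequency,
    the mean vector length R, the applied delay and the mode.  Fully
    deterministic given ``seed`` (defaults to ``params.seed``).

    The phase-delayed mode holds the stimulus *behind* the breather by
    the synchronization-gated delay, which pulls an entrained
    breather's onsets later and thus lowers its rate.
    """
    schedule = schedule or build_schedule()
    tracker_cfg = tracker_cfg or TrackerConfig()
    coupling_cfg = coupling_cfg or CouplingConfig()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    dt = coupling_cfg.dt
    n_steps = int(round(schedule.total / dt))
    default_freq = 1.0 / tracker_cfg.default_period
    stim = Oscillator(phase=0.0, natural_freq=default_freq, current_freq=default_freq)
    tracker: BreathState = new_state(tracker_cfg)
    sync = SyncWindow(coupling_cfg.sync_window)
    breather = BreatherState(last_time=0.0, next_kind=OnsetKind.INHALE, ratio=params.intrinsic_ratio)

    events: list[OnsetEvent] = []
    rows = []
    pending: OnsetEvent | None = None
    R = 0.0

    def stim_phase_extrapolate(t0, phase0, freq0):
        return lambda tq: (phase0 + 360.0 * freq0 * (tq - t0)) % 360.0

    # First onset: breather starts a cycle within the first seconds.
    first = float(rng.uniform(0.5, 2.0))
    pending = OnsetEvent(time=first, kind=OnsetKind.INHALE)

    for k in range(n_steps):
        t = k * dt
        mode = schedule.mode_at(t)
        audio_on = mode is not AlignmentMode.SILENCE

        # Emit breather onsets that fall inside this step.
        while pending is not None and pending.time <= t:
            events.append(pending)
            tracker, _ = ingest_onset(tracker, tracker_cfg, pending)
            breather_after = BreatherState(
                last_time=pending.time,
                next_kind=(
                    OnsetKind.EXHALE
                    if pending.kind is OnsetKind.INHALE
                    else OnsetKind.INHALE
                ),
                ratio=breather.ratio,
            )
            phase_fn = stim_phase_extrapolate(t, stim.phase, stim.current_freq)
            pending, breather = next_onset(
                breather_after,
                params,
                phase_fn,
                t,
                rng,
                entrain_active=audio_on,
                exhale_landmark=tracker_cfg.exhale_phase,
                stim_ratio=stim_ratio,
            )

        breather_phase = (
            phase_at(tracker, tracker_cfg, t) if tracker.has_onset else 0.0
        )
        sync.push(t, breather_phase, stim.phase)
        R = sync.mean_vector_length()
        cmd = target_offset(mode, R, coupling_cfg)
        # Delay convention: the stimulus lags the breather by the delay.
        offset = -cmd.offset if mode is AlignmentMode.PHASE_DELAYED else cmd.offset
        breather_freq = 1.0 / tracker.period if tracker.has_onset else None
        stim = kuramoto_step(
            stim,
            breather_phase,
            offset,
            coupling_cfg,
            breather_freq=breather_freq,
            phase_coupling=cmd.phase_coupling,
            freq_coupling=cmd.freq_coupling,
        )

        if k % trace_stride == 0:
            rows.append(
                (t, breather_phase, stim.phase, stim.current_freq, R,
                 cmd.offset, mode.value)
            )

    trace = pd.DataFrame(
        rows,
        columns=["time", "breather_phase", "stim_phase", "stim_freq", "R",
                 "delay", "mode"],
    )
    events = [e for e in events if e.time < schedule.total]
    return SessionLog(events=events, trace=trace, schedule=schedule, params=params)


def mean_rate_in(log: SessionLog, t0: float, t1: float) -> float:
    """Mean breathing rate (breaths/min) from inhale onsets in [t0, t1)."""
    inh = [e.time for e in log.events if e.kind is OnsetKind.INHALE and t0 <= e.time < t1]
    if len(inh) < 2:
        return float("nan")
    return 60.0 * (len(inh) - 1) / (inh[-1] - inh[0])
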
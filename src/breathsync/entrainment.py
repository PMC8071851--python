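"""Stimulus oscillator: Kuramoto coupling, synchronization, phase delay.

The stimulus is a single phase oscillator coupled to the tracked
breathing phase through the two-oscillator Kuramoto (Adler) equation

    dtheta/dt = 2*pi*f + K * sin(theta_target - theta)      [radians]

with ``theta_target`` the breather's phase plus a mode-dependent offset.
With a frequency detuning ``df`` the pair phase-locks iff ``K >=
2*pi*|df|``, settling at a constant offset ``arcsin(2*pi*df/K)``.  A
second, independent channel pulls the oscillator's frequency toward the
breather's observed frequency (first-order relaxation with rate
``freq_adapt``), giving the smooth tempo adaptation of the original
system.

Synchronization is quantified by the mean resultant vector length R of
the phase differences over a trailing window; during the phase-delayed
mode the stimulus is held *behind* the breather by a delay that grows
with R, from 0 up to ``delay_max`` (default 50 degrees).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .scheduler import AlignmentMode


@dataclass(frozen=True)
class Oscillator:
    """Stimulus phase oscillator state.

    ``natural_freq`` and ``current_freq`` are in Hz (breath cycles per
    second); ``phase`` is in degrees in [0, 360).
    """

    phase: float
    natural_freq: float
    current_freq: float

    def __post_init__(self) -> None:
        if self.natural_freq <= 0 or self.current_freq <= 0:
            raise ValueError("oscillator frequencies must be positive")


@dataclass(frozen=True)
class CouplingConfig:
    """Kuramoto coupling and delay-gate parameters.

    coupling : Kuramoto K, rad/s equivalent (1/seconds); 0 disables
        phase coupling.
    dt : explicit-Euler integration step, seconds.
    delay_max : upper bound of the synchronization-gated delay, degrees.
    delay_gate : 'linear' (delay = R * delay_max, default) or 'inverse'
        (delay = (1 - R) * delay_max).
    freq_adapt : rate (1/s) at which current_freq relaxes toward the
        breather's frequency when tempo coupling is active.
    sync_window : trailing window length for R, seconds.
    """

    coupling: float = 0.5
    dt: float = 0.01
    delay_max: float = 50.0
    delay_gate: str = "linear"
    freq_adapt: float = 0.2
    sync_window: float = 15.0

    def __post_init__(self) -> None:
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.delay_max < 360.0:
            raise ValueError("delay_max must be in [0, 360)")
        if self.delay_gate not in ("linear", "inverse"):
            raise ValueError("delay_gate must be 'linear' or 'inverse'")
        if self.sync_window <= 0:
            raise ValueError("sync_window must be positive")


class SyncWindow:
    """Trailing window of (breather_phase, stimulus_phase) samples.

    Maintains a running complex sum of exp(i * (phi_breath - phi_stim))
    so the mean vector length is O(1) per pushed sample.
    """

    def __init__(self, window_len: float):
        if window_len <= 0:
            raise ValueError("window_len must be positive")
        self.window_len = window_len
        self._samples: deque[tuple[float, complex]] = deque()
        self._sum: complex = 0.0 + 0.0j

    def __len__(self) -> int:
        return len(self._samples)

    def push(self, t: float, breather_phase: float, stim_phase: float) -> None:
        d = math.radians(breather_phase - stim_phase)
        z = complex(math.cos(d), math.sin(d))
        self._samples.append((t, z))
        self._sum += z
        cutoff = t - self.window_len
        while self._samples and self._samples[0][0] < cutoff:
            _, old = self._samples.popleft()
            self._sum -= old

    @property
    def phase_pairs(self) -> int:
        return len(self._samples)

    def mean_vector_length(self) -> float:
        return mean_vector_length_from_sum(self._sum, len(self._samples))


def mean_vector_length_from_sum(z_sum: complex, n: int) -> float:
    if n < 1:
        raise ValueError("mean vector length requires at least one sample")
    # Running-sum rounding can push |z|/n a hair above 1.
    return min(1.0, abs(z_sum) / n)


def mean_vector_length(
    breather_phases: np.ndarray, stim_phases: np.ndarray
) -> float:
    """Mean resultant length R of the pairwise phase differences.

    R = | mean_k exp(i * (phi_breath,k - phi_stim,k)) |, in [0, 1].
    1 means a perfectly consistent phase relation (locked), 0 none.
    Invariant under a common rotation of both phase vectors.
    """
    b = np.asarray(breather_phases, dtype=float)
    s = np.asarray(stim_phases, dtype=float)
    if b.size == 0:
        raise ValueError("mean vector length requires at least one sample")
    if b.shape != s.shape:
        raise ValueError("phase vectors must have equal length")
    z = np.exp(1j * np.deg2rad(b - s))
    return min(1.0, float(np.abs(z.mean())))


def phase_delay(R: float, cfg: CouplingConfig) -> float:
    """Synchronization-gated phase delay in degrees.

    Monotone map of R in [0, 1] onto [0, delay_max]; linear by default.
    """
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R must lie in [0, 1], got {R}")
    if cfg.delay_gate == "inverse":
        d = (1.0 - R) * cfg.delay_max
    else:
        d = R * cfg.delay_max
    return min(max(d, 0.0), cfg.delay_max)


@dataclass(frozen=True)
class CouplingCommand:
    """How the Kuramoto step should act for the current alignment mode.

    ``offset`` is the target offset in degrees fed to the phase channel;
    the closed-loop driver negates the delay (stimulus lags breather).
    """

    phase_coupling: bool
    freq_coupling: bool
    offset: float


def target_offset(
    mode: AlignmentMode, R: float, cfg: CouplingConfig
) -> CouplingCommand:
    """Per-mode coupling command.

    silence: no coupling at all; tempo_only: frequency channel only;
    phase_and_tempo: both channels, offset 0; phase_delayed: both
    channels with offset = phase_delay(R).
    """
    if mode is AlignmentMode.SILENCE:
        return CouplingCommand(False, False, 0.0)
    if mode is AlignmentMode.TEMPO_ONLY:
        return CouplingCommand(False, True, 0.0)
    if mode is AlignmentMode.PHASE_AND_TEMPO:
        return CouplingCommand(True, True, 0.0)
    if mode is AlignmentMode.PHASE_DELAYED:
        return CouplingCommand(True, True, phase_delay(R, cfg))
    raise ValueError(f"unknown alignment mode {mode!r}")


def kuramoto_step(
    stim: Oscillator,
    breather_phase: float,
    target_offset: float,
    cfg: CouplingConfig,
    breather_freq: float | None = None,
    phase_coupling: bool = True,
    freq_coupling: bool = True,
) -> Oscillator:
    """One explicit-Euler step of the coupled stimulus oscillator.

    Phase channel: dtheta/dt = 2*pi*current_freq + K*sin(theta_t - theta)
    with theta_t = breather_phase + target_offset (all angles handled in
    radians inside the kernel, degrees outside).  Frequency channel:
    current_freq relaxes toward ``breather_freq`` at rate
    ``cfg.freq_adapt`` when tempo coupling is active.  With coupling
    disabled the oscillator free-runs and its frequency never changes.
    """
    theta = math.radians(stim.phase)
    dtheta = 2.0 * math.pi * stim.current_freq
    if phase_coupling and cfg.coupling > 0.0:
        target = math.radians(breather_phase + target_offset)
        dtheta += cfg.coupling * math.sin(target - theta)
    new_phase = (stim.phase + math.degrees(dtheta) * cfg.dt) % 360.0

    new_freq = stim.current_freq
    if freq_coupling and breather_freq is not None and cfg.freq_adapt > 0.0:
        new_freq += cfg.freq_adapt * (breather_freq - new_freq) * cfg.dt
        new_freq = max(new_freq, 1e-6)
    return replace(stim, phase=new_phase, current_freq=new_freq)
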
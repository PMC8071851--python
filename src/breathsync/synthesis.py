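"""Stimulus rendering: breath-like noise, nature ambience, musical phrase.

Three stimulus families share one control signal, the stimulus
oscillator's phase trajectory:

* noise -- amplitude- and low-pass-modulated pink noise imitating a
  human breath sound, with smooth raised-cosine ramps toward each
  onset and a 1:2 inhale:exhale design ratio;
* nature -- an ambient scene whose wind-blown-leaves layer sits on
  eight equally spaced azimuths of a circle whose radius follows the
  breathing phase (rendered here as stereo width/gain, a deliberate
  simplification of the original ambisonic playback);
* music -- a descending arpeggio and ii-V-I progression of a
  marimba-like sound spanning the exhale (two thirds of the cycle),
  fading out quickly if an inhale arrives early, layered on the noise
  stimulus.

All renders are deterministic given (config, seed, phase trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

# ---------------------------------------------------------------- containers


@dataclass(frozen=True)
class SynthesisConfig:
    """Rendering parameters; all exposed, defaults chosen for smoothness.

    The phase axis is split at ``split_phase`` degrees: phases below it
    belong to the inhale sub-envelope, phases at or above to the exhale
    sub-envelope.  The split derives from ``target_ratio`` (exhale over
    inhale, default the healthy 2.0), giving 120 degrees: a
    constant-rate phase trajectory then spends exactly twice as long in
    the exhale sound as in the inhale sound.  Cutoff range 200 Hz -
    4 kHz spans a plausible breath-noise brightness sweep.
    """

    sample_rate: int = 44100
    control_rate: float = 100.0
    target_ratio: float = 2.0
    amp_trough: float = 0.05
    amp_peak: float = 1.0
    cutoff_min: float = 200.0
    cutoff_max: float = 4000.0
    fade: float = 0.150
    radius_min: float = 0.2
    radius_max: float = 1.0
    expand_on_inhale: bool = True
    # Music: descending C-major arpeggio then Dm7-G7-Cmaj7 (MIDI numbers).
    arpeggio: tuple[int, ...] = (84, 79, 76, 72)
    chords: tuple[tuple[int, ...], ...] = (
        (50, 57, 60, 65),  # Dm7
        (43, 55, 59, 65),  # G7
        (48, 55, 60, 64),  # Cmaj7
    )
    master_peak: float = 0.99

    @property
    def split_phase(self) -> float:
        return 360.0 / (1.0 + self.target_ratio)


@dataclass(frozen=True)
class NoteEvent:
    onset: float
    duration: float
    pitch: int  # MIDI note number
    velocity: float = 1.0


@dataclass
class StimulusControl:
    """Control-rate trajectories driving the audio render."""

    times: np.ndarray
    amp: np.ndarray
    cutoff: np.ndarray
    radius: np.ndarray | None = None
    notes: list[NoteEvent] | None = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.amp) == len(self.cutoff)):
            raise ValueError("times, amp, cutoff must have equal length")
        if np.any(self.amp < 0) or np.any(self.amp > 1):
            raise ValueError("amp envelope must lie in [0, 1]")


@dataclass
class AudioBuffer:
    """PCM audio; samples shape (n,) mono or (n, 2) stereo, in [-1, 1]."""

    sample_rate: int
    samples: np.ndarray

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sample_rate


def write_wav(buf: AudioBuffer, path) -> None:
    """Write 16-bit PCM WAV; bit-stable for identical buffers."""
    clipped = np.clip(buf.samples, -1.0, 1.0)
    wavfile.write(path, buf.sample_rate, (clipped * 32767.0).astype(np.int16))


def read_wav(path) -> AudioBuffer:
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    return AudioBuffer(sample_rate=rate, samples=data)


# ---------------------------------------------------------------- pink noise

# Kellet/Cooper economy pink filter: 1/f magnitude within a fraction of
# a dB from ~10 Hz to Nyquist at 44.1 kHz.
_PINK_B = (0.049922035, -0.095993537, 0.050612699, -0.004408786)
_PINK_A = (1.0, -2.494956002, 2.017265875, -0.522189400)


def generate_pink_noise(
    n: int, seed: int, sample_rate: int = 44100, rms: float = 0.2
) -> AudioBuffer:
    """1/f-spectrum noise (-3 dB/octave power slope) from filtered white.

    Deterministic given ``seed``; normalized to the requested RMS.
    A short warm-up segment is discarded so the IIR transient does not
    color the start of the buffer.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    warmup = 2048
    white = rng.standard_normal(n + warmup)
    pink = signal.lfilter(_PINK_B, _PINK_A, white)[warmup:]
    pink -= pink.mean()  # DC removal; 1/f drift would otherwise bias it
    pink *= rms / np.sqrt(np.mean(pink**2))
    return AudioBuffer(sample_rate=sample_rate, samples=pink)


def spectral_slope_db_per_decade(
    buf: AudioBuffer, f_lo: float = 20.0, f_hi: float = 5000.0
) -> float:
    """Log-log regression slope of the Welch PSD between f_lo and f_hi.

    Pink noise measures about -10 dB/decade in power.
    """
    f, pxx = signal.welch(buf.samples, fs=buf.sample_rate, nperseg=8192)
    m = (f >= f_lo) & (f <= f_hi)
    logf = np.log10(f[m])
    logp = 10.0 * np.log10(pxx[m])
    slope = np.polyfit(logf, logp, 1)[0]
    return float(slope)


# ------------------------------------------------------------- breath shape


def breath_envelope(
    times: np.ndarray, phases: np.ndarray, cfg: SynthesisConfig | None = None
) -> StimulusControl:
    """Amplitude and cutoff trajectories from a phase trajectory.

    Each half-cycle gets a raised-cosine bump: minimum (the trough) at
    both region boundaries, a single peak mid-region.  The inhale
    sub-envelope spans phases [0, split_phase), the exhale sub-envelope
    [split_phase, 360); at the default 1:2 design ratio the split sits
    at 120 degrees, so a constant-rate phase spends twice as long in
    the exhale sound as in the inhale sound.
    """
    cfg = cfg or SynthesisConfig()
    phases = np.asarray(phases, dtype=float) % 360.0
    split = cfg.split_phase
    x = np.where(phases < split, phases / split, (phases - split) / (360.0 - split))
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))  # 0 at onsets, 1 mid-region
    amp = cfg.amp_trough + (cfg.amp_peak - cfg.amp_trough) * bump
    cutoff = cfg.cutoff_min + (cfg.cutoff_max - cfg.cutoff_min) * bump
    return StimulusControl(times=np.asarray(times, dtype=float), amp=amp, cutoff=cutoff)


def _upsample(control_times, control_values, n, sample_rate):
    t_audio = np.arange(n) / sample_rate
    return np.interp(t_audio, control_times, control_values)


def render_noise_stimulus(
    control: StimulusControl,
    noise: AudioBuffer,
    cfg: SynthesisConfig | None = None,
) -> AudioBuffer:
    """Amplitude-modulate and low-pass filter pink noise; stereo out.

    The time-varying low-pass is a one-pole whose coefficient is held
    per control-rate block (``y[i] = y[i-1] + a*(x[i]-y[i-1])`` with
    ``a = 1 - exp(-2*pi*fc/fs)``); at cutoffs at or above ~Nyquist the
    filter is bypassed.  A master peak clamp scales the result down if
    it would exceed ``cfg.master_peak`` (never up, so silence stays
    silence and passthrough stays passthrough).
    """
    cfg = cfg or SynthesisConfig()
    n = noise.samples.shape[0]
    fs = noise.sample_rate
    dur_control = control.times[-1] - control.times[0]
    if abs(dur_control - n / fs) > 0.5 + 2.0 / cfg.control_rate:
        raise ValueError("control trajectory and noise buffer duration mismatch")

    amp = _upsample(control.times, control.amp, n, fs)
    x = noise.samples * amp

    # Block-wise one-pole low-pass at the control rate.
    block = max(1, int(round(fs / cfg.control_rate)))
    cutoff = np.interp(
        control.times[0] + np.arange(math.ceil(n / block)) * block / fs,
        control.times,
        control.cutoff,
    )
    y = np.empty_like(x)
    y_last = 0.0
    nyq = fs / 2.0
    for k, fc in enumerate(cutoff):
        lo, hi = k * block, min((k + 1) * block, n)
        if hi <= lo:
            break
        if fc >= 0.99 * nyq:
            y[lo:hi] = x[lo:hi]
        else:
            a = 1.0 - math.exp(-2.0 * math.pi * fc / fs)
            zi = np.array([(1.0 - a) * y_last])
            seg, _ = signal.lfilter([a], [1.0, a - 1.0], x[lo:hi], zi=zi)
            y[lo:hi] = seg
        y_last = y[hi - 1]

    stereo = np.column_stack([y, y])
    return _master_clamp(AudioBuffer(sample_rate=fs, samples=stereo), cfg)


def _master_clamp(buf: AudioBuffer, cfg: SynthesisConfig) -> AudioBuffer:
    peak = float(np.max(np.abs(buf.samples))) if buf.samples.size else 0.0
    if peak > cfg.master_peak:
        buf.samples = buf.samples * (cfg.master_peak / peak)
    return buf


# ------------------------------------------------------------------- music


def compose_music_phrase(
    period: float, cfg: SynthesisConfig | None = None
) -> list[NoteEvent]:
    """Descending arpeggio + ii-V-I progression spanning the exhale.

    Total notated duration is (2/3) * period -- an exhale twice the
    inhale's length.  The arpeggio fills the first half of the span
    (equal note values), the three chords the second half; onsets and
    durations scale linearly with the period.
    """
    cfg = cfg or SynthesisConfig()
    if period <= 0:
        raise ValueError("period must be positive")
    span = (2.0 / 3.0) * period
    notes: list[NoteEvent] = []
    arp_dur = (span / 2.0) / len(cfg.arpeggio)
    for i, pitch in enumerate(cfg.arpeggio):
        notes.append(NoteEvent(onset=i * arp_dur, duration=arp_dur, pitch=pitch))
    chord_dur = (span / 2.0) / len(cfg.chords)
    for j, chord in enumerate(cfg.chords):
        onset = span / 2.0 + j * chord_dur
        for pitch in chord:
            notes.append(
                NoteEvent(onset=onset, duration=chord_dur, pitch=pitch, velocity=0.8)
            )
    return notes


def _midi_to_hz(pitch: int) -> float:
    return 440.0 * 2.0 ** ((pitch - 69) / 12.0)


def render_notes(
    notes: list[NoteEvent],
    duration: float,
    sample_rate: int = 44100,
    start: float = 0.0,
) -> AudioBuffer:
    """Render marimba-like notes: exponentially decaying partials.

    Partial ratios 1.0 / 3.9 / 9.2 approximate a struck wooden bar; the
    fundamental rings longest.
    """
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    partials = ((1.0, 1.0, 0.25), (3.9, 0.4, 0.08), (9.2, 0.15, 0.04))
    for note in notes:
        onset = note.onset + start
        i0 = int(round(onset * sample_rate))
        if i0 >= n:
            continue
        ring = min(max(note.duration * 1.5, 0.3), duration - onset)
        t = np.arange(int(ring * sample_rate)) / sample_rate
        f0 = _midi_to_hz(note.pitch)
        tone = np.zeros_like(t)
        for ratio, gain, tau in partials:
            tone += gain * np.exp(-t / tau) * np.sin(2 * np.pi * f0 * ratio * t)
        tone *= note.velocity * 0.2
        i1 = min(i0 + len(tone), n)
        out[i0:i1] += tone[: i1 - i0]
    return AudioBuffer(sample_rate=sample_rate, samples=out)


def apply_early_inhale_fadeout(
    audio: AudioBuffer, inhale_time: float, cfg: SynthesisConfig | None = None
) -> AudioBuffer:
    """Quickly fade the phrase stem when an inhale interrupts it.

    Linear gain ramp from 1 at ``inhale_time`` to 0 over ``cfg.fade``
    seconds; everything after the ramp is silenced.
    """
    cfg = cfg or SynthesisConfig()
    n = audio.samples.shape[0]
    i0 = int(round(inhale_time * audio.sample_rate))
    if not 0 <= i0 < n:
        raise ValueError("inhale_time outside the buffer")
    n_fade = max(1, int(round(cfg.fade * audio.sample_rate)))
    gain = np.ones(n)
    ramp_end = min(i0 + n_fade, n)
    gain[i0:ramp_end] = 1.0 - (np.arange(ramp_end - i0) / n_fade)
    gain[ramp_end:] = 0.0
    samples = audio.samples * (gain if audio.samples.ndim == 1 else gain[:, None])
    return AudioBuffer(sample_rate=audio.sample_rate, samples=samples)


# ------------------------------------------------------------------- nature

NATURE_AZIMUTHS_DEG = tuple(float(k * 45) for k in range(8))


def nature_radius(phase, cfg: SynthesisConfig | None = None):
    """Spatial radius of the leaves circle as a function of breath phase.

    Smooth cosine map of phase onto [radius_min, radius_max], one
    expansion/contraction per breath cycle; expands on inhale by
    default (maximum at phase 0).
    """
    cfg = cfg or SynthesisConfig()
    ph = np.deg2rad(np.asarray(phase, dtype=float))
    bump = 0.5 * (1.0 + np.cos(ph))  # 1 at inhale onset, 0 mid-cycle
    if not cfg.expand_on_inhale:
        bump = 1.0 - bump
    r = cfg.radius_min + (cfg.radius_max - cfg.radius_min) * bump
    return float(r) if np.isscalar(phase) else r


def _leaves_stem(n, rng, fs):
    # Band-passed noise with slow random amplitude: wind in foliage.
    noise = rng.standard_normal(n)
    sos = signal.butter(2, [500, 2500], btype="band", fs=fs, output="sos")
    x = signal.sosfilt(sos, noise)
    env_pts = 0.4 + 0.6 * rng.random(max(4, n // (2 * fs) + 2))
    env = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(env_pts)), env_pts)
    return x * env


def _chime_stem(n, rng, fs):
    out = np.zeros(n)
    n_strikes = max(1, int(n / fs / 4))
    pitches = np.array([880.0, 1174.7, 1318.5, 1760.0])
    for _ in range(n_strikes):
        i0 = rng.integers(0, max(1, n - fs))
        f = float(rng.choice(pitches))
        t = np.arange(min(2 * fs, n - i0)) / fs
        out[i0 : i0 + len(t)] += 0.3 * np.exp(-t / 0.8) * np.sin(2 * np.pi * f * t)
    return out


def _rain_stem(n, rng, fs):
    sos = signal.butter(2, 4000, btype="low", fs=fs, output="sos")
    return 0.5 * signal.sosfilt(sos, rng.standard_normal(n))


def _bird_stem(n, rng, fs):
    out = np.zeros(n)
    n_chirps = max(1, int(n / fs / 3))
    for _ in range(n_chirps):
        i0 = rng.integers(0, max(1, n - fs // 2))
        dur = int(0.15 * fs)
        t = np.arange(min(dur, n - i0)) / fs
        f0, f1 = rng.uniform(2500, 4000), rng.uniform(3500, 5500)
        sweep = np.sin(2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * 0.15)))
        out[i0 : i0 + len(t)] += 0.25 * np.hanning(len(t)) * sweep
    return out


def _equal_power_pan(mono: np.ndarray, position: np.ndarray) -> np.ndarray:
    """position in [-1, 1] (left..right), per-sample; equal-power law."""
    theta = (position + 1.0) * (np.pi / 4.0)
    return np.column_stack([mono * np.cos(theta), mono * np.sin(theta)])


def render_nature_stimulus(
    control: StimulusControl,
    duration: float,
    seed: int,
    cfg: SynthesisConfig | None = None,
) -> AudioBuffer:
    """Procedural ambient scene with phase-driven leaves circle.

    Eight independently modulated copies of the leaves stem sit at
    azimuths 0°, 45°, ..., 315°; the circle radius (from
    ``control.radius``) scales each copy's stereo pan position and
    gain -- a stereo stand-in for the original ambisonic radius.  The
    chimes, rain and bird stems sit at fixed asymmetric positions.
    Deterministic given seed.
    """
    cfg = cfg or SynthesisConfig()
    if control.radius is None:
        raise ValueError("nature rendering needs a radius trajectory")
    fs = cfg.sample_rate
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    radius = _upsample(control.times, control.radius, n, fs)
    amp = _upsample(control.times, control.amp, n, fs)

    out = np.zeros((n, 2))
    for az in NATURE_AZIMUTHS_DEG:
        stem = _leaves_stem(n, rng, fs)
        base_pos = math.sin(math.radians(az))  # front-circle projected to stereo
        pos = base_pos * radius
        gain = (0.3 + 0.7 * radius) * (0.4 + 0.6 * amp) / 8.0
        out += _equal_power_pan(stem * gain, pos)

    for stem_fn, pos in ((_chime_stem, -0.6), (_rain_stem, 0.3), (_bird_stem, 0.7)):
        stem = stem_fn(n, rng, fs)
        out += _equal_power_pan(stem * 0.15, np.full(n, pos))

    return _master_clamp(AudioBuffer(sample_rate=fs, samples=out), cfg)
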
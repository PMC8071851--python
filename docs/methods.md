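# Methods

This note documents the models, conventions and parameter choices
behind `breathsync`, in the order the data flows: onset tracking →
entrainment → scheduling → sound synthesis → virtual breather →
behavioral analysis.

## Breathing phase and tempo from onset events

The only behavioral input is a stream of timestamped inhale/exhale
keypresses. The tracker maps it to a continuously defined phase
θ_b(t) in degrees:

- at an accepted inhale onset, θ_b snaps to 0°; at an exhale onset, to
  `exhale_phase` (default **240°**);
- between onsets, θ_b advances linearly at 360°/period and wraps at
  360° with no lookahead — it may overshoot the next snap target and
  be corrected discontinuously at the onset.

The 240° exhale constant follows the original system's convention. It
is deliberately *not* the 120° value a 1:2 inhale:exhale geometry
would imply; the package keeps the constant configurable and does not
silently repair the discrepancy (see *Known tensions* below).

Tempo: the classic statistic is the median of the last five
inter-onset intervals (`median_ioi`), which mixes inhale→exhale and
exhale→inhale half-cycles. For the full-cycle period the package
prefers the median of recent **inhale-to-inhale** intervals, which is
independent of the inhale:exhale ratio, falling back to twice the
mixed-IOI median before two inhales exist, and to a default period of
5 s (12 breaths/min) before that. Onsets closer than a 0.2 s debounce
to the previous accepted press are rejected (keyboards double-fire);
non-monotone timestamps are rejected with a distinct signal.

## Kuramoto coupling and the synchronization-gated delay

The stimulus oscillator integrates, by explicit Euler at dt = 10 ms,

    dθ_s/dt = 2π f_s + K sin(θ_target − θ_s)          (radians)

with K = 0.5 s⁻¹ by default. A second, independent channel relaxes the
oscillator's frequency toward the breather's observed frequency at
rate η = 0.2 s⁻¹ (the "tempo alignment" channel); neither K, dt nor η
is prescribed by the original description, so all three are exposed in
`CouplingConfig`. The two-oscillator theory fixes the behavior the
implementation must reproduce: with frequency detuning Δf the pair
locks iff K ≥ 2π|Δf|, settling at offset arcsin(2πΔf/K); below
threshold the phase difference drifts without bound. The test suite
checks both regimes against these closed forms.

Synchronization is the circular mean resultant length R of the phase
differences over a trailing 15 s window (a few breath cycles; the
window length is a package choice). R = 1 means a perfectly consistent
phase relation, 0 none; R is invariant under common rotations of both
phase vectors.

**Phase-delay convention.** In the final trial segment the stimulus is
held *behind* the breather by a delay that grows with R — linearly
from 0° at R = 0 to 50° at R = 1 by default (an inverse map is also
provided). The sign is the package's design choice: a delay is only
worth applying once entrained, and a lagging stimulus pulls an
entrained breather's onsets later, lowering respiration rate toward
the ~6 breaths/min target. Internally the Kuramoto target is
`θ_b − delay` during the phase-delayed mode.

## Trial schedule

Default 480 s timeline: silence 60 s → tempo-only 60 s →
phase-and-tempo 180 s → phase-delayed 180 s. Segments are half-open
`[start, end)`; a boundary instant belongs to the later segment.
Boundaries are cumulative sums computed once, so queries are bit-stable.

## Stimulus synthesis

All three families are driven by the stimulus phase trajectory at a
100 Hz control rate and rendered at 44.1 kHz, deterministically given
(config, seed, trajectory); a master peak clamp scales output down
(never up) to |sample| ≤ 0.99.

**Noise.** Pink noise (Kellet economy IIR on white noise, 1/f within a
fraction of a dB across the audio band; DC removed, RMS-normalized) is
amplitude-modulated and low-pass filtered. Both trajectories are
raised-cosine bumps per half-cycle: troughs (amp 0.05) at the region
boundaries — the ramps point *toward* each onset — and one peak per
region; the cutoff sweeps 200 Hz–4 kHz with the same shape. The
time-varying low-pass is a one-pole whose coefficient is held per
control-rate block; at cutoffs near Nyquist it is bypassed. The phase
axis splits into inhale/exhale sub-envelopes at
`split = 360°/(1 + target_ratio)` = **120°** for the 1:2 design
ratio, so a constant-rate phase spends exactly twice as long in the
exhale sound. (Splitting at the tracker's 240° constant instead would
produce a 2:1 sound — see *Known tensions*.)

**Nature.** Eight independently modulated copies of a procedural
wind-blown-leaves stem (band-passed noise with slow random amplitude)
sit at azimuths 0°, 45°, …, 315°; the circle radius follows a smooth
cosine of the breath phase between 0.2 and 1.0, expanding on inhale by
default. Chime, rain and bird stems (decaying sinusoids, low-passed
noise, frequency-swept chirps) sit at fixed asymmetric positions. The
original ambisonic/HRTF rendering is deliberately simplified to
equal-power stereo panning with width and gain scaled by the radius;
this preserves the control signals, not the spatial percept. The
procedural stems are synthetic stand-ins so no sample downloads are
needed; file-based stems can be substituted upstream of the renderer.

**Music.** A descending arpeggio (C6–G5–E5–C5) followed by a
Dm7–G7–Cmaj7 progression of a marimba-like tone (decaying partials at
ratios 1.0/3.9/9.2), spanning (2/3)·period — an exhale twice the
inhale — with onsets scaling linearly with period. An early inhale
triggers a 150 ms linear fade of the phrase stem. Key, voicing and
fade are configurable; the defaults are package choices.

## Virtual breather

An onset-level model: the next onset time is the intrinsic
continuation (from `intrinsic_rate` and the current exhale:inhale
ratio) blended with weight `entrain_gain` toward the stimulus's
corresponding alignment cue, plus Gaussian jitter truncated at ±3 SD
(preventing interval collapse; a 0.3 s physiological floor guards the
rest). The ratio drifts toward the sound's design ratio (2.0) with
`ratio_gain` per cycle.

The alignment cues are the stimulus phase's crossings of **0° and
240°** — the tracker's snap constants — because in perfect lock those
coincide with the breather's own presses, so the phase delay shifts
both cues uniformly later. (Using the envelope's 120° sound split
instead mixes an early exhale cue with a late inhale cue and largely
cancels the delay; both conventions were simulated, and the cue-based
one is the default.)

Defaults emulate a relaxed but not-yet-slow participant:
8 breaths/min, ratio 1.5, jitter SD 0.15 s, entrain gain 0.3. The
per-onset convex blend produces Arnold-tongue-like behavior: within
the locking range the breather converges to the stimulus tempo
regardless of gain; the gain controls the transient, which is why the
"rate strictly between intrinsic and stimulus" property is checked
over a 20-cycle window from rest.

What the simulation does *not* model: respiratory mechanics, CO₂
chemoreflexes, heart-rate variability, attention lapses, or any
auditory perception — the breather reads the oscillator's phase, not
the audio. Passing closed-loop tests therefore demonstrate the
*control system's* behavior under an idealized responsive participant,
not human efficacy.

## Behavioral analysis

Per trial: inter-onset times (IOTs) between consecutive presses, and
per-cycle exhale:inhale ratios from proper inhale→exhale→inhale
triples (a missing or doubled press voids that cycle's ratio only).
The outlier rule discards a value deviating from the mean of the
previous 6-keypress window's five *surviving* values by more than
5 sample SDs; if that SD is below 1e-9 (constant window) any deviation
above 1e-9 is discarded; the first window is never discarded; the
skipped fraction is reported in percent. The rule operates on raw
values, not windowed medians (the ambiguity is flagged for sensitivity
analysis). Note that against a strongly alternating IOT background the
window SD is of the order of the half-cycle asymmetry and the rule is
intentionally permissive; it bites on near-constant streams.

Rate uses full inhale-to-inhale cycles inside each 6-keypress window,
60·(n_inhales − 1)/(span of inhales) breaths/min, with the window
stamped at its median event time; the mixed-IOT median is kept for the
tempo tracker only. Series are linearly interpolated onto a 0.1 Hz
grid (48 samples per 480 s trial; edges held), log-transformed
(natural log), and fit by least squares on an orthonormal polynomial
basis of degree 4 (QR of the centered-index Vandermonde; Gram identity
to machine precision). The regression design rescales the constant
column to ones, so the intercept is the mean log value and the
time-term columns stay orthonormal. With condition labels, fits are
pooled per condition. Participant-level random effects are out of
scope; `tidy_table` emits a long-format table for external
mixed-effects software.

## Known tensions, inherited deliberately

The original convention snaps the exhale at 240° while describing the
sound as designed for a 1:2 inhale:exhale ratio, which implies 120°.
The package keeps both: tracking/alignment uses 240°, sound-envelope
geometry uses 120°, each configurable. Two measurable consequences are
reproduced rather than hidden: (1) a tracker-warped phase of a true
1:2 breather winds through the inhale region twice per cycle; (2) in
closed loop the 240° cue geometry implies a 2:1 exhale:inhale pull
while the ratio-drift channel pulls toward 2.0, so an entrained
virtual breather settles near a compromise ratio (~1.5 under
defaults) instead of the 2.0 target.

## Problem sizes and numerics

Closed-loop sessions integrate 480 s at 10 ms steps; the seed-sweep
experiments (rate recovery, delay direction-of-effect) use 20 seeds
each. Pink-noise spectral checks use 2²⁰ samples with Welch
periodograms (8192-point segments) and a log-log regression over
20 Hz–5 kHz. The Adler-offset checks integrate 200 s at 5 ms. Angles
are degrees everywhere except inside trigonometric kernels; the
running circular sum in the synchronization window is clamped to
R ≤ 1 against floating-point drift.
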
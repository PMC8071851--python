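"""Trial timeline of alignment modes.

A session is 8 minutes: 1 min of silence, then 7 min of audio in which
the stimulus is tempo-aligned for 1 min, phase- and tempo-aligned for
3 min, and phase-delayed for 3 min.  Segments are half-open intervals
[start, end); a boundary instant belongs to the later segment.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass, field


class AlignmentMode(enum.Enum):
    SILENCE = "silence"
    TEMPO_ONLY = "tempo_only"
    PHASE_AND_TEMPO = "phase_and_tempo"
    PHASE_DELAYED = "phase_delayed"


DEFAULT_SEGMENTS: tuple[tuple[AlignmentMode, float], ...] = (
    (AlignmentMode.SILENCE, 60.0),
    (AlignmentMode.TEMPO_ONLY, 60.0),
    (AlignmentMode.PHASE_AND_TEMPO, 180.0),
    (AlignmentMode.PHASE_DELAYED, 180.0),
)


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered, contiguous alignment-mode segments.

    Boundaries are cumulative sums computed once at construction, so
    repeated queries never re-accumulate floating point error.
    """

    segments: tuple[tuple[AlignmentMode, float], ...]
    boundaries: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        bounds = []
        acc = 0.0
        for mode, dur in self.segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be positive, got {dur}")
            if not isinstance(mode, AlignmentMode):
                raise TypeError(f"not an AlignmentMode: {mode!r}")
            acc += dur
            bounds.append(acc)
        object.__setattr__(self, "boundaries", tuple(bounds))

    @property
    def total(self) -> float:
        return self.boundaries[-1]

    def mode_at(self, t: float) -> AlignmentMode:
        """Alignment mode of the segment containing time ``t``.

        Half-open segments: a segment boundary belongs to the later
        segment.  ``t`` outside [0, total) is an error.
        """
        if not 0.0 <= t < self.total:
            raise ValueError(f"t={t} outside schedule [0, {self.total})")
        idx = bisect_right(self.boundaries, t)
        return self.segments[idx][0]

    def segment_interval(self, mode: AlignmentMode) -> tuple[float, float]:
        """[start, end) of the first segment with the given mode."""
        start = 0.0
        for (m, dur), end in zip(self.segments, self.boundaries):
            if m is mode:
                return start, end
            start = end
        raise KeyError(f"mode {mode} not in schedule")


def build_schedule(
    segments: list[tuple[AlignmentMode | str, float]] | None = None,
) -> SessionSchedule:
    """Build a session schedule; defaults to the 480 s trial timeline."""
    if segments is None:
        return SessionSchedule(DEFAULT_SEGMENTS)
    norm = tuple(
        (m if isinstance(m, AlignmentMode) else AlignmentMode(m), float(d))
        for m, d in segments
    )
    return SessionSchedule(norm)


def mode_at(schedule: SessionSchedule, t: float) -> AlignmentMode:
    """Functional alias for :meth:`SessionSchedule.mode_at`."""
    return schedule.mode_at(t)
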
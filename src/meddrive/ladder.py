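"""Exposure-duration ladder for the visual recognition task.

The battery presents stimuli for durations drawn from a fixed, roughly
log-spaced ladder of frame-quantized exposure times.  At a 60 Hz refresh
rate the 19 rungs run from one frame (16.7 ms) up to 278 frames
(4633.3 ms); on faster displays the same frame-count pattern is scaled by
the shorter frame period, so the fastest rung drops to 8.3 ms at 120 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Frame counts of the 19 ladder rungs.  Multiplying by the frame period
#: (16.67 ms at 60 Hz) reproduces the canonical duration list
#: 16.7, 33.3, 50, ..., 3500, 4633.3 ms.
FRAME_PATTERN: tuple[int, ...] = (
    1, 2, 3, 4, 5, 7, 9, 13, 17, 22, 29, 39, 51, 68, 90, 119, 158, 210, 278,
)


@dataclass(frozen=True)
class DurationLadder:
    """Ordered set of permissible stimulus exposure durations.

    Attributes
    ----------
    durations : tuple of float
        Strictly increasing exposure durations in milliseconds, each an
        integer multiple of the frame period (reported to 0.1 ms).
    frame_ms : float
        Exact display frame period in milliseconds.
    """

    durations: tuple[float, ...]
    frame_ms: float
    log_durations: tuple[float, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "log_durations", tuple(np.log(self.durations).tolist())
        )

    def __len__(self) -> int:
        return len(self.durations)

    def duration(self, index: int) -> float:
        return self.durations[index]

    def log_step_width(self, index: int) -> float:
        """Local log-spacing of the ladder around ``index``.

        Returns the larger of the two adjacent log-duration gaps (one gap
        at the ends).  Used to express estimator error in 'ladder steps'.
        """
        logs = self.log_durations
        gaps = []
        if index > 0:
            gaps.append(logs[index] - logs[index - 1])
        if index < len(logs) - 1:
            gaps.append(logs[index + 1] - logs[index])
        return max(gaps)

    def nearest_index(self, duration_ms: float) -> int:
        """Ladder index whose log-duration is closest to ``duration_ms``."""
        logs = np.asarray(self.log_durations)
        return int(np.argmin(np.abs(logs - np.log(duration_ms))))


def build_ladder(frame_ms: float = 1000.0 / 60.0) -> DurationLadder:
    """Build the exposure-duration ladder for a given display frame period.

    ``frame_ms`` is snapped to the nearest integer refresh rate when the
    nominal rate is within 2% of one (so the conventional shorthand 16.7 ms
    resolves to the exact 60 Hz period of 16.666... ms, and 8.3 ms to
    120 Hz).  Durations are the frame-count pattern times the exact frame
    period, reported to 0.1 ms as the instrument prints them.

    Parameters
    ----------
    frame_ms : float
        Display frame period in milliseconds; must be positive.

    Returns
    -------
    DurationLadder
    """
    if not np.isfinite(frame_ms) or frame_ms <= 0:
        raise InvalidArgumentError(f"frame_ms must be positive, got {frame_ms!r}")
    hz = 1000.0 / frame_ms
    hz_int = round(hz)
    if hz_int >= 1 and abs(hz - hz_int) / hz_int < 0.02:
        exact = 1000.0 / hz_int
    else:
        exact = float(frame_ms)
    durations = tuple(round(n * exact, 1) for n in FRAME_PATTERN)
    return DurationLadder(durations=durations, frame_ms=exact)
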
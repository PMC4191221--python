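"""Raw task outcomes from trial-level session logs.

Each task's outcome is a robust summary of its response series: the worst
measures are dropped to discount attentional slips, a within-session
learning trend (linear in the log of the trial number, reflecting the
logarithmic shape of practice curves) is regressed out and the series
re-anchored at end-of-session performance, and the remaining values are
averaged — arithmetically for response times, geometrically for the
localization errors and exposure thresholds whose noise is multiplicative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    MalformedSessionError,
)

ATTENTION_CONDITIONS: tuple[str, ...] = ("neutral", "alerting", "orientation")

#: Response times above this many milliseconds are counted as lapses
#: (e.g. the space bar pressed too softly and repeated after 1-2 s).
DEFAULT_SLIP_THRESHOLD_MS = 2000.0


@dataclass(frozen=True)
class RTTrial:
    """One speeded trial of the attention (cueing) or movement task."""

    trial_number: int
    condition: str
    rt_ms: float
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise InvalidArgumentError(f"rt_ms must be positive, got {self.rt_ms}")


@dataclass(frozen=True)
class MemoryTrial:
    """One series of the spatial working-memory task.

    ``err_first_mm`` / ``err_last_mm`` are the Euclidean distances from
    the true to the reported position of the first and last cross;
    ``n_crosses`` is the series length (set size), 2-7.
    """

    trial_number: int
    n_crosses: int
    err_first_mm: float
    err_last_mm: float

    def __post_init__(self) -> None:
        if not 2 <= self.n_crosses <= 7:
            raise InvalidArgumentError(
                f"n_crosses must be in [2, 7], got {self.n_crosses}"
            )
        if self.err_first_mm < 0 or self.err_last_mm < 0:
            raise InvalidArgumentError("localization errors must be >= 0")


@dataclass
class TaskOutcomes:
    """The raw battery outcomes plus auxiliary measures.

    Times in ms, distances in mm.  ``decay_slope`` is the slope of log
    first-cue error on set size; ``decay_slope_defined`` is False when all
    retained series share one set size.  ``lapse_counts`` maps task name
    to the number of slip/incorrect trials.
    """

    central_ms: float | None = None
    peripheral_ms: float | None = None
    dual_ms: float | None = None
    rt_neutral_ms: float | None = None
    rt_alerting_ms: float | None = None
    rt_orientation_ms: float | None = None
    alerting_gain_ms: float | None = None
    orientation_gain_ms: float | None = None
    movement_rt_ms: float | None = None
    mem_first_mm: float | None = None
    mem_last_mm: float | None = None
    decay_slope: float | None = None
    decay_slope_defined: bool = True
    lapse_counts: dict[str, int] = field(default_factory=dict)

    #: Outcome fields entering the seven-score vector, in canonical order.
    SCORED_FIELDS = (
        "central_ms",
        "peripheral_ms",
        "dual_ms",
        "rt_orientation_ms",
        "movement_rt_ms",
        "mem_first_mm",
        "mem_last_mm",
    )


# ---------------------------------------------------------------------------
# primitive operations


def remove_worst_indices(values: Sequence[float], k: int) -> list[int]:
    """Positions retained after dropping the ``k`` largest values.

    Ties are broken by dropping the later measurement.  Retained positions
    are returned in original order.
    """
    vals = np.asarray(values, dtype=float)
    if k < 0 or k >= len(vals):
        raise InvalidArgumentError(
            f"k must satisfy 0 <= k < {len(vals)}, got {k}"
        )
    if k == 0:
        return list(range(len(vals)))
    # ascending by value, then by position: the last k entries are the
    # worst, with later trials removed first among ties
    order = np.lexsort((np.arange(len(vals)), vals))
    dropped = set(order[len(vals) - k:].tolist())
    return [i for i in range(len(vals)) if i not in dropped]


def remove_worst(values: Sequence[float], k: int) -> list[float]:
    """Drop the ``k`` largest values (slowest RTs / largest errors)."""
    vals = list(values)
    return [vals[i] for i in remove_worst_indices(vals, k)]


def fit_learning_trend(
    values: Sequence[float], trial_numbers: Sequence[float]
) -> tuple[float, float]:
    """OLS fit of value on ln(trial number); returns (slope, intercept)."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(trial_numbers, dtype=float)
    if len(y) < 3:
        raise InsufficientDataError(
            f"learning fit needs >= 3 points, got {len(y)}"
        )
    x = np.log(t)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("trial numbers carry no variance")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def adjust_learning(
    values: Sequence[float],
    trial_numbers: Sequence[float],
    anchor: float | None = None,
) -> tuple[np.ndarray, float]:
    """Remove the within-session learning trend from a response series.

    Fits ``value ~ ln(trial_number)`` by ordinary least squares and
    returns the residuals re-centered at the fitted value of the anchor
    trial (default: the last trial number), i.e. the series as if every
    measurement had been taken at end-of-session practice level.

    Returns
    -------
    (adjusted, slope)
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(trial_numbers, dtype=float)
    slope, intercept = fit_learning_trend(y, t)
    if anchor is None:
        anchor = float(t[-1])
    fitted = intercept + slope * np.log(t)
    adjusted = y - fitted + (intercept + slope * math.log(anchor))
    return adjusted, slope


# ---------------------------------------------------------------------------
# task scoring


def _check_conditions(trials: Sequence[RTTrial], n_per_condition: int) -> None:
    counts = {c: 0 for c in ATTENTION_CONDITIONS}
    for tr in trials:
        if tr.condition not in counts:
            raise MalformedSessionError(f"unknown condition {tr.condition!r}")
        counts[tr.condition] += 1
    bad = {c: n for c, n in counts.items() if n != n_per_condition}
    if bad:
        raise MalformedSessionError(
            f"expected {n_per_condition} trials per condition, got {bad}"
        )


def score_attention(
    trials: Sequence[RTTrial],
    n_per_condition: int = 32,
    n_remove: int = 3,
    removal: Literal["per_condition", "pooled_two_slowest"] = "per_condition",
) -> TaskOutcomes:
    """Condition means and cueing gains for the central cue attention task.

    Per condition (neutral / alerting / orientation): the worst (slowest)
    measures are removed, the learning trend over the session-wide trial
    index is regressed out with the series re-anchored at the final trial,
    and the mean adjusted RT is taken.  Gains are neutral minus cued
    condition means.  ``removal="pooled_two_slowest"`` selects the variant
    that drops only the two slowest measurements of the whole block.
    """
    _check_conditions(trials, n_per_condition)
    anchor = max(tr.trial_number for tr in trials)
    if removal == "pooled_two_slowest":
        keep = remove_worst_indices([tr.rt_ms for tr in trials], 2)
        pool = [trials[i] for i in keep]
        retained = {
            c: [tr for tr in pool if tr.condition == c]
            for c in ATTENTION_CONDITIONS
        }
    elif removal == "per_condition":
        retained = {}
        for c in ATTENTION_CONDITIONS:
            sub = [tr for tr in trials if tr.condition == c]
            keep = remove_worst_indices([tr.rt_ms for tr in sub], n_remove)
            retained[c] = [sub[i] for i in keep]
    else:
        raise InvalidArgumentError(f"unknown removal mode {removal!r}")

    means: dict[str, float] = {}
    for c, sub in retained.items():
        adjusted, _ = adjust_learning(
            [tr.rt_ms for tr in sub],
            [tr.trial_number for tr in sub],
            anchor=anchor,
        )
        means[c] = float(adjusted.mean())
    return TaskOutcomes(
        rt_neutral_ms=means["neutral"],
        rt_alerting_ms=means["alerting"],
        rt_orientation_ms=means["orientation"],
        alerting_gain_ms=means["neutral"] - means["alerting"],
        orientation_gain_ms=means["neutral"] - means["orientation"],
    )


def score_movement(
    trials: Sequence[RTTrial],
    n_correct: int = 40,
    n_remove: int = 4,
    n_learning: int = 30,
) -> float:
    """Adjusted mean response time of the movement detection task.

    Takes the first ``n_correct`` correct trials, removes the ``n_remove``
    slowest, fits the learning trend on the first ``n_learning`` retained
    measures (indexed by retained order), adjusts all retained measures to
    the final retained index, and returns the mean in ms.
    """
    correct = [tr for tr in trials if tr.correct]
    if len(correct) < n_correct:
        raise MalformedSessionError(
            f"need {n_correct} correct trials, got {len(correct)}"
        )
    correct = correct[:n_correct]
    keep = remove_worst_indices([tr.rt_ms for tr in correct], n_remove)
    rts = np.array([correct[i].rt_ms for i in keep])
    order = np.arange(1, len(rts) + 1, dtype=float)
    n_fit = min(n_learning, len(rts))
    slope, intercept = fit_learning_trend(rts[:n_fit], order[:n_fit])
    anchor = order[-1]
    adjusted = rts - (intercept + slope * np.log(order)) + (
        intercept + slope * math.log(anchor)
    )
    return float(adjusted.mean())


def score_memory(
    trials: Sequence[MemoryTrial],
    n_trials: int = 30,
    n_remove: int = 3,
) -> tuple[float, float, float | None]:
    """Geometric-mean localization errors and the memory-decay slope.

    Separately for the first and last cue: the ``n_remove`` largest errors
    are dropped, errors are log-transformed, the learning trend is
    regressed out (anchored at the final series), and the mean log is
    exponentiated back to mm.  The decay slope is the OLS slope of the
    retained log first-cue errors on the number of crosses; it is
    ``None`` when all retained series share one set size.

    Returns
    -------
    (mem_first_mm, mem_last_mm, decay_slope)
    """
    if len(trials) != n_trials:
        raise MalformedSessionError(
            f"expected {n_trials} memory series, got {len(trials)}"
        )
    anchor = max(tr.trial_number for tr in trials)
    geo: dict[str, float] = {}
    first_keep: list[int] = []
    for cue in ("first", "last"):
        errs = [
            tr.err_first_mm if cue == "first" else tr.err_last_mm
            for tr in trials
        ]
        keep = remove_worst_indices(errs, n_remove)
        if cue == "first":
            first_keep = keep
        logs = np.log(np.maximum([errs[i] for i in keep], 1e-9))
        adjusted, _ = adjust_learning(
            logs, [trials[i].trial_number for i in keep], anchor=anchor
        )
        geo[cue] = float(np.exp(adjusted.mean()))
    x = np.array([trials[i].n_crosses for i in first_keep], dtype=float)
    y = np.log(np.maximum([trials[i].err_first_mm for i in first_keep], 1e-9))
    if np.ptp(x) == 0:
        slope = None
    else:
        slope = float(np.polyfit(x, y, 1)[0])
    return geo["first"], geo["last"], slope


def count_lapses(
    trials: Iterable[RTTrial],
    slip_threshold_ms: float = DEFAULT_SLIP_THRESHOLD_MS,
    count_incorrect: bool = False,
) -> int:
    """Number of slip trials: RT above the threshold, plus (for the
    movement task) incorrect responses."""
    n = 0
    for tr in trials:
        if tr.rt_ms > slip_threshold_ms:
            n += 1
        elif count_incorrect and tr.correct is False:
            n += 1
    return n
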
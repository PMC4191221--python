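"""Interleaved three-subtask adaptive staircase for the visual recognition task.

The task interleaves three subtasks (central, peripheral, dual) in random
order, each tracked by its own one-up/one-down staircase on the shared
exposure-duration ladder: a correct answer shortens the next exposure of
that subtask by one rung, a wrong answer lengthens it by one rung, clamped
at both ends of the ladder.  The session may end only after 60 stimuli in
total, and only once every subtask has produced at least three upper and
three lower reversals whose most recent three of each kind sit within a
span of three consecutive ladder positions.  The threshold for a subtask
is the geometric mean of the learning-adjusted exposure durations after
its first reversal, which estimates the 50% point of the underlying
psychometric function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    InvalidArgumentError,
    NonConvergenceError,
    NoThresholdError,
)
from .ladder import DurationLadder, build_ladder
from .scoring import fit_learning_trend

SUBTASKS: tuple[str, ...] = ("central", "peripheral", "dual")

#: (trial_number, ladder_index, correct)
TrialTuple = tuple[int, int, bool]


@dataclass(frozen=True)
class StaircaseState:
    """Position and history of one subtask's staircase.

    ``history`` holds one ``(trial_number, ladder_index, correct)`` tuple
    per presented stimulus; ``index`` is the rung the *next* stimulus will
    use.  Reversal bookkeeping is a pure function of ``history`` (see
    :func:`detect_reversals`).
    """

    subtask: str
    ladder: DurationLadder
    index: int
    history: tuple[TrialTuple, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.subtask not in SUBTASKS:
            raise InvalidArgumentError(f"unknown subtask {self.subtask!r}")
        if not 0 <= self.index < len(self.ladder):
            raise InvalidArgumentError(
                f"index {self.index} outside ladder bounds [0, {len(self.ladder) - 1}]"
            )

    @property
    def reversals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        return detect_reversals(self.history)


def new_state(
    subtask: str, ladder: DurationLadder | None = None, start_index: int = 9
) -> StaircaseState:
    """Fresh staircase for ``subtask`` starting mid-ladder by default."""
    if ladder is None:
        ladder = build_ladder()
    return StaircaseState(subtask=subtask, ladder=ladder, index=start_index)


def step_ladder(
    state: StaircaseState, correct: bool, trial_number: int | None = None
) -> StaircaseState:
    """Record a response at the current rung and move the staircase.

    The stimulus is presented at ``state.index``; a correct answer moves
    the next presentation one rung down (shorter exposure), a wrong answer
    one rung up, clamped to the ladder bounds.  Returns a new state; the
    input is not mutated.
    """
    if trial_number is None:
        trial_number = (state.history[-1][0] + 1) if state.history else 1
    presented = state.index
    nxt = presented - 1 if correct else presented + 1
    nxt = min(max(nxt, 0), len(state.ladder) - 1)
    return replace(
        state,
        index=nxt,
        history=state.history + ((trial_number, presented, bool(correct)),),
    )


def detect_reversals(
    history: Sequence[TrialTuple],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Locate upper and lower reversals in a staircase history.

    An upper reversal is a trial where the presented ladder index is a
    local maximum of the staircase path (movement switches from up to
    down); a lower reversal is a local minimum.  A plateau produced by
    clamping at a ladder bound counts as a single reversal attributed to
    the first clamped trial.

    Returns
    -------
    (upper, lower) : pair of lists of ``(trial_number, ladder_index)``.
    """
    upper: list[tuple[int, int]] = []
    lower: list[tuple[int, int]] = []
    if len(history) < 3:
        return upper, lower
    direction = 0  # sign of the last non-zero index movement
    ext_pos = 0  # position where the current run's extremum first occurred
    indices = [h[1] for h in history]
    for i in range(1, len(indices)):
        d = indices[i] - indices[i - 1]
        if d == 0:
            continue
        d = 1 if d > 0 else -1
        if direction == 0:
            direction = d
            ext_pos = i
            continue
        if d != direction:
            trial, idx, _ = history[ext_pos]
            if direction > 0:
                upper.append((trial, idx))
            else:
                lower.append((trial, idx))
            direction = d
        ext_pos = i
    return upper, lower


def _reversals_stable(
    state: StaircaseState, n_each: int = 3, span: int = 3
) -> bool:
    """Most recent ``n_each`` upper and lower reversals within ``span``
    consecutive ladder positions."""
    upper, lower = detect_reversals(state.history)
    if len(upper) < n_each or len(lower) < n_each:
        return False
    idxs = [i for _, i in upper[-n_each:]] + [i for _, i in lower[-n_each:]]
    return max(idxs) - min(idxs) <= span - 1


def check_termination(
    states: Iterable[StaircaseState],
    total_trials: int,
    min_trials: int = 60,
) -> bool:
    """Whether the visual recognition task may end.

    True iff at least ``min_trials`` stimuli have been shown in total and
    every subtask's staircase has stabilized: at least three upper and
    three lower reversals, with the most recent three of each kind all at
    ladder indices spanning no more than three consecutive positions.
    """
    by_subtask = {s.subtask: s for s in states}
    missing = set(SUBTASKS) - set(by_subtask)
    if missing:
        raise InvalidArgumentError(f"missing subtask state(s): {sorted(missing)}")
    if total_trials < min_trials:
        return False
    return all(_reversals_stable(by_subtask[s]) for s in SUBTASKS)


def select_subtask(
    rng: np.random.Generator,
    single_subtask: str | None = None,
) -> str:
    """Draw the next subtask uniformly at random (or a fixed one in
    single-subtask mode)."""
    if single_subtask is not None:
        if single_subtask not in SUBTASKS:
            raise InvalidArgumentError(f"unknown subtask {single_subtask!r}")
        return single_subtask
    return SUBTASKS[int(rng.integers(0, len(SUBTASKS)))]


def estimate_threshold(
    state: StaircaseState,
    learning_fit: str = "all",
) -> float:
    """Estimate the subtask's 50% exposure-duration threshold in ms.

    Restricts the history to trials strictly after the first reversal,
    removes the within-session learning trend (an ordinary least-squares
    fit of log-duration on log trial number, re-anchored at the last
    trial), and returns the geometric mean of the adjusted durations.

    Parameters
    ----------
    state : StaircaseState
        Staircase with at least one reversal.
    learning_fit : {"all", "post"}
        Whether the learning trend is fitted on all trials of the subtask
        or only on the post-first-reversal trials used in the average.

    Raises
    ------
    NoThresholdError
        If the history contains no reversal, or no trials follow it.
    """
    if learning_fit not in ("all", "post"):
        raise InvalidArgumentError(f"learning_fit must be 'all' or 'post'")
    upper, lower = detect_reversals(state.history)
    reversal_trials = [t for t, _ in upper] + [t for t, _ in lower]
    if not reversal_trials:
        raise NoThresholdError(
            f"{state.subtask}: no reversal in {len(state.history)} trials"
        )
    first = min(reversal_trials)
    post = [h for h in state.history if h[0] > first]
    if not post:
        raise NoThresholdError(f"{state.subtask}: no trials after first reversal")
    logs = np.array([state.ladder.log_durations[i] for _, i, _ in post])
    trials = np.array([t for t, _, _ in post], dtype=float)
    if learning_fit == "all":
        fit_logs = np.array(
            [state.ladder.log_durations[i] for _, i, _ in state.history]
        )
        fit_trials = np.array([t for t, _, _ in state.history], dtype=float)
    else:
        fit_logs, fit_trials = logs, trials
    anchor = float(state.history[-1][0])
    if len(fit_trials) >= 3 and np.ptp(np.log(fit_trials)) > 0:
        slope, intercept = fit_learning_trend(fit_logs, fit_trials)
        x = np.log(trials)
        adjusted = logs - (intercept + slope * x) + (intercept + slope * math.log(anchor))
    else:
        adjusted = logs
    return float(np.exp(adjusted.mean()))


def run_visual_task(
    responder: Callable[[str, float, int], bool],
    ladder: DurationLadder | None = None,
    rng: np.random.Generator | None = None,
    start_index: int = 9,
    min_trials: int = 60,
    max_trials: int = 600,
    single_subtask: str | None = None,
    n_trials: int | None = None,
) -> dict[str, StaircaseState]:
    """Run the interleaved staircase controller against a responder.

    ``responder(subtask, duration_ms, trial_number) -> correct`` supplies
    the answer to each stimulus (a simulated observer, or a scripted
    policy).  The loop ends at the first trial where
    :func:`check_termination` is satisfied; in single-subtask mode only
    that subtask's reversal criteria (plus the minimum trial count) are
    required.  Passing ``n_trials`` disables the termination rule and runs
    a fixed number of stimuli instead (used for stationarity analyses).

    Raises
    ------
    NonConvergenceError
        If ``max_trials`` stimuli pass without meeting the rule.
    """
    if ladder is None:
        ladder = build_ladder()
    if rng is None:
        rng = np.random.default_rng()
    subtasks = (single_subtask,) if single_subtask else SUBTASKS
    states = {s: new_state(s, ladder, start_index) for s in subtasks}
    cap = n_trials if n_trials is not None else max_trials
    for t in range(1, cap + 1):
        sub = select_subtask(rng, single_subtask)
        st = states[sub]
        duration = ladder.duration(st.index)
        correct = bool(responder(sub, duration, t))
        states[sub] = step_ladder(st, correct, trial_number=t)
        if n_trials is None:
            if single_subtask:
                done = t >= min_trials and _reversals_stable(states[single_subtask])
            else:
                done = check_termination(states.values(), t, min_trials)
            if done:
                return states
    if n_trials is not None:
        return states
    raise NonConvergenceError(
        f"staircase did not meet the termination rule within {max_trials} trials"
    )
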
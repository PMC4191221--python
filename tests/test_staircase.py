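import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meddrive as md
from meddrive.staircase import (
    SUBTASKS,
    _reversals_stable,
    detect_reversals,
    new_state,
    run_visual_task,
    step_ladder,
)


def play(corrects, start_index=9, ladder=None):
    """Run a correctness sequence through one staircase."""
    state = new_state("central", ladder, start_index)
    for i, c in enumerate(corrects, start=1):
        state = step_ladder(state, c, trial_number=i)
    return state


# ---------------------------------------------------------------------------
# stepping


def test_correct_steps_down_wrong_steps_up(ladder60):
    state = new_state("central", ladder60, start_index=5)
    assert step_ladder(state, True).index == 4
    assert step_ladder(state, False).index == 6


def test_clamping_at_ladder_bounds(ladder60):
    bottom = new_state("central", ladder60, start_index=0)
    assert step_ladder(bottom, True).index == 0
    top = new_state("central", ladder60, start_index=18)
    assert step_ladder(top, False).index == 18


@given(st.lists(st.booleans(), min_size=1, max_size=200))
def test_staircase_never_leaves_ladder_bounds(corrects):
    state = play(corrects)
    indices = [idx for _, idx, _ in state.history] + [state.index]
    assert all(0 <= i <= 18 for i in indices)


# ---------------------------------------------------------------------------
# reversal detection


def brute_force_reversals(history):
    """Independent oracle: local extrema of the run-compressed index path,
    each attributed to the first trial of its plateau."""
    runs = []  # (index value, position of first trial in the run)
    for pos, (_, idx, _) in enumerate(history):
        if not runs or runs[-1][0] != idx:
            runs.append((idx, pos))
    upper, lower = [], []
    for k in range(1, len(runs) - 1):
        v, pos = runs[k]
        trial, idx, _ = history[pos]
        if v > runs[k - 1][0] and v > runs[k + 1][0]:
            upper.append((trial, idx))
        elif v < runs[k - 1][0] and v < runs[k + 1][0]:
            lower.append((trial, idx))
    return upper, lower


def test_trough_is_a_lower_reversal():
    # index path 5,4,3,4: one lower reversal at the trough (index 3)
    state = play([True, True, False, True], start_index=5)
    upper, lower = detect_reversals(state.history)
    assert upper == []
    assert lower == [(3, 3)]


def test_monotone_descent_has_no_reversals():
    state = play([True] * 6)
    assert detect_reversals(state.history) == ([], [])


def test_alternating_answers_reverse_at_every_interior_trial():
    state = play([True, False] * 5)
    upper, lower = detect_reversals(state.history)
    trials = sorted(t for t, _ in upper + lower)
    assert trials == list(range(2, 10))


def test_clamped_plateau_counts_once_at_first_clamped_trial():
    # from index 1: correct x4 pins the staircase at 0, then a wrong answer
    state = play([True, True, True, True, False, False], start_index=1)
    upper, lower = detect_reversals(state.history)
    assert lower == [(2, 0)]
    assert upper == []


def test_reversal_detection_matches_brute_force_exhaustively():
    for n in (3, 6, 10):
        for corrects in itertools.product([True, False], repeat=n):
            state = play(corrects, start_index=3)
            assert detect_reversals(state.history) == brute_force_reversals(
                state.history
            ), corrects


# ---------------------------------------------------------------------------
# termination rule


def alternating_states(ladder, n_per_subtask=24):
    """Each subtask alternates wrong/correct: reversals at every interior
    trial, all within two adjacent ladder indices."""
    states = {}
    t = 0
    seqs = {s: [] for s in SUBTASKS}
    for i in range(n_per_subtask):
        for s in SUBTASKS:
            t += 1
            seqs[s].append((t, i % 2 == 1))
    for s in SUBTASKS:
        state = new_state(s, ladder)
        for trial, c in seqs[s]:
            state = step_ladder(state, c, trial_number=trial)
        states[s] = state
    return states, t


def test_termination_needs_sixty_stimuli(ladder60):
    states, _ = alternating_states(ladder60)
    assert md.check_termination(states.values(), total_trials=59) is False
    assert md.check_termination(states.values(), total_trials=60) is True


def test_termination_requires_tight_reversals(ladder60):
    states, total = alternating_states(ladder60)
    # wide staircase: descend 6, climb 6, repeatedly -> reversals 6 apart
    wide = new_state("central", ladder60, start_index=12)
    t = 0
    for _ in range(4):
        for c in [True] * 6 + [False] * 6:
            t += 1
            wide = step_ladder(wide, c, trial_number=t)
    upper, lower = detect_reversals(wide.history)
    assert len(upper) >= 3 and len(lower) >= 3
    states["central"] = wide
    assert md.check_termination(states.values(), total_trials=100) is False


def test_termination_missing_subtask_rejected(ladder60):
    states, _ = alternating_states(ladder60)
    del states["dual"]
    with pytest.raises(md.InvalidArgumentError):
        md.check_termination(states.values(), total_trials=80)


# ---------------------------------------------------------------------------
# subtask selection


def test_subtask_selection_deterministic_and_uniform():
    seqs = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        seqs.append([md.select_subtask(rng) for _ in range(6000)])
    assert seqs[0] == seqs[1]
    for s in SUBTASKS:
        assert abs(seqs[0].count(s) / 6000 - 1 / 3) < 0.02
    rng = np.random.default_rng(1)
    assert all(
        md.select_subtask(rng, single_subtask="dual") == "dual" for _ in range(10)
    )


# ---------------------------------------------------------------------------
# threshold estimation


def test_constant_post_reversal_durations_give_that_duration(ladder60):
    # two descents then wrong/correct alternation pinned between rungs 6, 7
    state = play([True, True, True] + [False, True] * 10, start_index=9)
    est = md.estimate_threshold(state, learning_fit="post")
    logs = [
        ladder60.log_durations[6],
        ladder60.log_durations[7],
    ]
    assert np.log(est) == pytest.approx(np.mean(logs), abs=0.25)


def test_flat_history_single_duration_geometric_mean(ladder60):
    # alternation from the start: post-reversal trials sit on rungs 8 and 9
    state = play([False, True] * 15, start_index=9)
    est = md.estimate_threshold(state, learning_fit="post")
    assert (
        ladder60.durations[8] * 0.8 <= est <= ladder60.durations[9] * 1.2
    )


def test_no_reversal_raises_no_threshold_error():
    state = play([True] * 8)
    with pytest.raises(md.NoThresholdError):
        md.estimate_threshold(state)


def test_threshold_recovery_against_effective_fifty_percent_point(ladder60):
    """Median log error over simulated observers stays within one
    ladder-step log width of the effective 50% point."""
    rng = np.random.default_rng(5)
    errors = []
    for i in range(60):
        theta = float(np.exp(rng.uniform(np.log(30), np.log(1000))))
        prof = md.ObserverProfile(
            thresholds_ms={s: theta for s in SUBTASKS},
            slip_prob=0.0,
            learning={},
        )
        gamma = prof.guess_rates["central"]
        lam = prof.lapse_rate
        # p(t) = 0.5 at ln t = ln theta + sigma * logit((0.5-g)/(1-g-l))
        z = np.log((0.5 - gamma) / (1 - gamma - lam) / (1 - (0.5 - gamma) / (1 - gamma - lam)))
        log_t50 = np.log(theta) + prof.slope_sigma * z
        obs = np.random.default_rng(100 + i)
        states = run_visual_task(
            lambda s, d, t: obs.random() < md.p_correct(prof, s, d),
            ladder=ladder60,
            rng=np.random.default_rng(i),
            single_subtask="central",
            n_trials=200,
        )
        est = md.estimate_threshold(states["central"])
        step = ladder60.log_step_width(ladder60.nearest_index(np.exp(log_t50)))
        errors.append(abs(np.log(est) - log_t50) / step)
    assert np.median(errors) <= 1.0


def test_controller_nonconvergence_raises(ladder60):
    # an observer answering at chance never stabilizes low reversal spans
    rng = np.random.default_rng(3)
    with pytest.raises(md.NonConvergenceError):
        run_visual_task(
            lambda s, d, t: bool(rng.random() < 0.5),
            ladder=ladder60,
            rng=np.random.default_rng(0),
            max_trials=80,
        )


def test_reversal_stability_helper(ladder60):
    states, _ = alternating_states(ladder60)
    assert _reversals_stable(states["central"]) is True
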
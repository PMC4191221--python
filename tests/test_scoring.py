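import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meddrive as md
from meddrive.scoring import (
    ATTENTION_CONDITIONS,
    MemoryTrial,
    RTTrial,
    remove_worst_indices,
)


# ---------------------------------------------------------------------------
# worst-measure removal


@pytest.mark.parametrize(
    "values, k, expected",
    [
        ([300, 900, 310, 320], 1, [300, 310, 320]),
        ([300, 900, 310, 320], 0, [300, 900, 310, 320]),
        ([5, 5, 5], 1, [5, 5]),  # tie: the later trial is dropped
        ([2, 9, 9, 1], 1, [2, 9, 1]),
    ],
)
def test_remove_worst(values, k, expected):
    assert md.remove_worst(values, k) == expected


def test_remove_worst_tie_drops_later_trial():
    assert remove_worst_indices([5, 5, 5], 1) == [0, 1]
    assert remove_worst_indices([7, 7, 3], 2) == [2]


@pytest.mark.parametrize("k", [-1, 3, 5])
def test_remove_worst_invalid_k(k):
    with pytest.raises(md.InvalidArgumentError):
        md.remove_worst([1.0, 2.0, 3.0], k)


# ---------------------------------------------------------------------------
# learning adjustment


def test_constant_series_is_unchanged():
    adjusted, slope = md.adjust_learning([4.0] * 10, range(1, 11))
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert adjusted == pytest.approx([4.0] * 10)


def test_exact_log_linear_series_collapses_to_anchor_value():
    t = np.arange(1, 31)
    values = 10.0 - 2.0 * np.log(t)
    adjusted, slope = md.adjust_learning(values, t, anchor=30)
    assert slope == pytest.approx(-2.0)
    assert adjusted == pytest.approx(np.full(30, 10.0 - 2.0 * math.log(30)))


def test_learning_adjustment_error_paths():
    with pytest.raises(md.InsufficientDataError):
        md.adjust_learning([1.0, 2.0], [1, 2])
    with pytest.raises(md.DegenerateDesignError):
        md.adjust_learning([1.0, 2.0, 3.0], [4, 4, 4])


@given(
    shift=st.floats(min_value=-100, max_value=100),
    seed=st.integers(min_value=0, max_value=50),
)
def test_adjustment_commutes_with_constant_shift(shift, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(400, 30, size=20)
    t = np.arange(1, 21)
    base, _ = md.adjust_learning(values, t)
    shifted, _ = md.adjust_learning(values + shift, t)
    assert shifted == pytest.approx(base + shift, abs=1e-8)


# ---------------------------------------------------------------------------
# attention task


def make_attention(rts_by_condition, n=32):
    trials = []
    t = 0
    for i in range(n):
        for cond in ATTENTION_CONDITIONS:
            t += 1
            rts = rts_by_condition[cond]
            rt = rts[i] if hasattr(rts, "__len__") else rts
            trials.append(RTTrial(t, cond, rt))
    return trials


def test_constant_rts_give_equal_means_and_zero_gains():
    trials = make_attention({c: 400.0 for c in ATTENTION_CONDITIONS})
    out = md.score_attention(trials)
    for v in (out.rt_neutral_ms, out.rt_alerting_ms, out.rt_orientation_ms):
        assert v == pytest.approx(400.0)
    assert out.alerting_gain_ms == pytest.approx(0.0)
    assert out.orientation_gain_ms == pytest.approx(0.0)


def test_gains_are_neutral_minus_condition_mean():
    trials = make_attention(
        {"neutral": 350.0, "alerting": 330.0, "orientation": 320.0}
    )
    out = md.score_attention(trials)
    assert out.orientation_gain_ms == pytest.approx(
        out.rt_neutral_ms - out.rt_orientation_ms
    )
    assert out.orientation_gain_ms == pytest.approx(30.0)
    assert out.alerting_gain_ms == pytest.approx(20.0)


def test_wrong_trial_count_is_malformed():
    trials = make_attention({c: 400.0 for c in ATTENTION_CONDITIONS})
    with pytest.raises(md.MalformedSessionError):
        md.score_attention(trials[:-1])


def test_pooled_two_slowest_variant():
    trials = make_attention({c: 400.0 for c in ATTENTION_CONDITIONS})
    # two extreme slips land in the neutral condition
    slow = [i for i, tr in enumerate(trials) if tr.condition == "neutral"][:2]
    for i in slow:
        trials[i] = RTTrial(trials[i].trial_number, "neutral", 5000.0)
    out = md.score_attention(trials, removal="pooled_two_slowest")
    assert out.rt_neutral_ms == pytest.approx(400.0)


# ---------------------------------------------------------------------------
# movement task


def test_constant_movement_rts():
    trials = [RTTrial(i, "congruent", 800.0, True) for i in range(1, 41)]
    assert md.score_movement(trials) == pytest.approx(800.0)


def test_movement_slips_removed_and_series_anchored():
    # four slips first, then a series exactly log-linear in retained order
    trials = [RTTrial(i, "congruent", 5000.0, True) for i in range(1, 5)]
    trials += [
        RTTrial(i + 4, "congruent", 1200.0 - 100.0 * math.log(i), True)
        for i in range(1, 37)
    ]
    out = md.score_movement(trials)
    assert out == pytest.approx(1200.0 - 100.0 * math.log(36), abs=1e-9)


def test_too_few_correct_trials_is_malformed():
    trials = [RTTrial(i, "congruent", 700.0, True) for i in range(1, 40)]
    trials.append(RTTrial(40, "congruent", 700.0, False))
    with pytest.raises(md.MalformedSessionError):
        md.score_movement(trials)


def test_incorrect_trials_do_not_enter_the_outcome():
    trials = []
    t = 0
    for i in range(1, 41):
        t += 1
        trials.append(RTTrial(t, "congruent", 9000.0, False))
        t += 1
        trials.append(RTTrial(t, "congruent", 800.0, True))
    assert md.score_movement(trials) == pytest.approx(800.0)


# ---------------------------------------------------------------------------
# memory task


def make_memory(err_fn, n=30):
    return [
        MemoryTrial(i, 2 + (i % 6), *err_fn(i, 2 + (i % 6))) for i in range(1, n + 1)
    ]


def test_constant_errors_give_that_distance_and_zero_slope():
    trials = make_memory(lambda i, n: (10.0, 10.0))
    first, last, slope = md.score_memory(trials)
    assert first == pytest.approx(10.0)
    assert last == pytest.approx(10.0)
    assert slope == pytest.approx(0.0, abs=1e-9)


def test_exact_decay_slope_recovered():
    trials = make_memory(lambda i, n: (math.exp(1.5 + 0.2 * n), 8.0))
    _, _, slope = md.score_memory(trials)
    assert slope == pytest.approx(0.2, abs=1e-6)


def test_single_set_size_flags_undefined_slope():
    trials = [MemoryTrial(i, 4, 10.0 + i * 0.1, 8.0) for i in range(1, 31)]
    first, last, slope = md.score_memory(trials)
    assert slope is None
    assert first > 0 and last > 0


def test_memory_outcomes_scale_with_distances():
    trials = make_memory(lambda i, n: (5.0 + 0.3 * i, 4.0 + 0.2 * i))
    f1, l1, _ = md.score_memory(trials)
    scaled = [
        MemoryTrial(t.trial_number, t.n_crosses, 3.0 * t.err_first_mm, 3.0 * t.err_last_mm)
        for t in trials
    ]
    f3, l3, _ = md.score_memory(scaled)
    assert f3 == pytest.approx(3.0 * f1)
    assert l3 == pytest.approx(3.0 * l1)


def test_wrong_memory_trial_count_is_malformed():
    with pytest.raises(md.MalformedSessionError):
        md.score_memory([MemoryTrial(1, 3, 5.0, 5.0)] * 10)


# ---------------------------------------------------------------------------
# lapse counting


def test_count_lapses():
    trials = [RTTrial(1, "neutral", 400.0), RTTrial(2, "neutral", 5000.0)]
    assert md.count_lapses(trials) == 1
    assert md.count_lapses(trials, slip_threshold_ms=float("inf")) == 0
    movement = trials + [RTTrial(3, "congruent", 600.0, False)]
    assert md.count_lapses(movement, count_incorrect=True) == 2
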
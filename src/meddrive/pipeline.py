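"""End-to-end scoring: session record in, outcomes and scores out."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .errors import MalformedSessionError
from .ladder import build_ladder
from .scoring import (
    MemoryTrial,
    RTTrial,
    TaskOutcomes,
    count_lapses,
    score_attention,
    score_memory,
    score_movement,
)
from .session import SessionRecord
from .staircase import SUBTASKS, StaircaseState, estimate_threshold
from .transform import SCORE_NAMES, ScoreVector, score_outcomes

#: raw outcome field -> canonical score name
OUTCOME_TO_SCORE = {
    "central_ms": "central",
    "peripheral_ms": "peripheral",
    "dual_ms": "dual",
    "rt_orientation_ms": "orientation_cue",
    "movement_rt_ms": "movement",
    "mem_first_mm": "memory_first",
    "mem_last_mm": "memory_last",
}


def _staircase_states(record: SessionRecord) -> dict[str, StaircaseState]:
    ladder = build_ladder(record.environment.frame_ms)
    states: dict[str, StaircaseState] = {}
    for sub in SUBTASKS:
        rows = [r for r in record.visual_trials if r.subtask == sub]
        if not rows:
            raise MalformedSessionError(f"no visual trials for subtask {sub!r}")
        history = tuple(
            (r.trial_number, r.ladder_index, r.correct)
            for r in sorted(rows, key=lambda r: r.trial_number)
        )
        states[sub] = StaircaseState(
            subtask=sub, ladder=ladder, index=history[-1][1], history=history
        )
    return states


def score_session(
    record: SessionRecord,
    learning_fit: str = "all",
    attention_removal: str = "per_condition",
) -> TaskOutcomes:
    """Compute all raw task outcomes for one session record."""
    states = _staircase_states(record)
    thresholds = {
        sub: estimate_threshold(states[sub], learning_fit=learning_fit)
        for sub in SUBTASKS
    }
    attention = [
        RTTrial(r.trial_number, r.condition, r.rt_ms, r.correct)
        for r in record.attention_trials
    ]
    movement = [
        RTTrial(r.trial_number, r.condition, r.rt_ms, r.correct)
        for r in record.movement_trials
    ]
    memory = [
        MemoryTrial(r.trial_number, r.n_crosses, r.err_first_mm, r.err_last_mm)
        for r in record.memory_trials
    ]
    att = score_attention(attention, removal=attention_removal)  # type: ignore[arg-type]
    movement_rt = score_movement(movement)
    mem_first, mem_last, decay = score_memory(memory)
    return TaskOutcomes(
        central_ms=thresholds["central"],
        peripheral_ms=thresholds["peripheral"],
        dual_ms=thresholds["dual"],
        rt_neutral_ms=att.rt_neutral_ms,
        rt_alerting_ms=att.rt_alerting_ms,
        rt_orientation_ms=att.rt_orientation_ms,
        alerting_gain_ms=att.alerting_gain_ms,
        orientation_gain_ms=att.orientation_gain_ms,
        movement_rt_ms=movement_rt,
        mem_first_mm=mem_first,
        mem_last_mm=mem_last,
        decay_slope=decay,
        decay_slope_defined=decay is not None,
        lapse_counts={
            "attention": count_lapses(attention),
            "movement": count_lapses(movement, count_incorrect=True),
        },
    )


def outcomes_to_score_inputs(outcomes: TaskOutcomes) -> dict[str, float]:
    return {
        OUTCOME_TO_SCORE[f]: getattr(outcomes, f) for f in TaskOutcomes.SCORED_FIELDS
    }


def compute_scores(
    outcomes: TaskOutcomes, weights: Mapping[str, float] | None = None
) -> ScoreVector:
    """Seven [0, 1] scores and the 0-100 composite from raw outcomes."""
    return score_outcomes(outcomes_to_score_inputs(outcomes), weights)


def score_cohort(
    records: Sequence[SessionRecord],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Score many sessions into a tidy table.

    One row per session: the raw outcomes, the seven scores (x100 as
    printed) and the composite, plus the recorded age when the session
    was simulated from a profile.
    """
    rows = []
    for rec in records:
        outcomes = score_session(rec)
        sv = compute_scores(outcomes, weights)
        row: dict[str, object] = {"session_id": rec.session_id}
        if rec.profile is not None and "age" in rec.profile:
            row["age"] = rec.profile["age"]
        for f in (
            "central_ms", "peripheral_ms", "dual_ms", "rt_neutral_ms",
            "rt_alerting_ms", "rt_orientation_ms", "alerting_gain_ms",
            "orientation_gain_ms", "movement_rt_ms", "mem_first_mm",
            "mem_last_mm", "decay_slope",
        ):
            row[f] = getattr(outcomes, f)
        for name in SCORE_NAMES:
            row[f"score_{name}"] = 100.0 * sv.scores[name]
        row["composite"] = sv.composite
        rows.append(row)
    return pd.DataFrame(rows)
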
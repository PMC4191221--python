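"""Virtual participants: generative models for complete battery sessions.

An :class:`ObserverProfile` holds the generative counterparts of every
scored outcome: per-subtask psychometric functions (logistic in
log-exposure-duration, with subtask-specific guess rates and a lapse
rate), shifted log-normal response times contaminated by occasional long
"slip" responses, log-normal spatial localization errors whose log-mean
grows with memory set size, and an exponentially decaying within-session
learning benefit per task.  :func:`simulate_session` runs the full
protocol — the interleaved staircase until its termination rule, 32
response times per cueing condition, movement-detection trials until 40
correct answers, and 30 spatial-memory series — and returns a session
record the scoring pipeline consumes.  :func:`generate_cohort` samples
age-structured cohorts whose composite score declines by roughly five
points per decade, the cross-sectional gradient the battery is designed
to detect.

All outputs are pure functions of (profile, seed): every task draws from
its own named substream spawned from the session seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import InvalidArgumentError, NonConvergenceError
from .ladder import build_ladder
from .session import (
    EnvironmentBlock,
    MemoryTrialRow,
    RTTrialRow,
    SessionRecord,
    VisualTrialRow,
)
from .staircase import SUBTASKS, run_visual_task

ATTENTION_CONDITIONS = ("neutral", "alerting", "orientation")
MOVEMENT_CONDITIONS = ("congruent", "incongruent")

#: Reference age (years) at which cohort age gradients vanish.
REFERENCE_AGE = 75.0


@dataclass(frozen=True)
class ObserverProfile:
    """Generative parameters of one simulated participant.

    Defaults describe a typical older driver in their mid-seventies:
    thresholds and response times sit near the middle of the retained
    score ranges.  Guess rates follow the response formats — one of five
    stimulus alternatives centrally, one of six arrows peripherally, and
    both judgments jointly (1/30) in the dual subtask.
    """

    # --- visual recognition (staircase) ---
    thresholds_ms: dict[str, float] = field(
        default_factory=lambda: {
            "central": 230.0, "peripheral": 280.0, "dual": 1800.0,
        }
    )
    #: logistic width on the log-duration axis (smaller = steeper)
    slope_sigma: float = 0.125
    guess_rates: dict[str, float] = field(
        default_factory=lambda: {
            "central": 1 / 5, "peripheral": 1 / 6, "dual": 1 / 30,
        }
    )
    lapse_rate: float = 0.02
    # --- attention (cueing) RTs: rt = shift + LogNormal(mu, sd) - gain ---
    rt_shift_ms: float = 180.0
    rt_log_mu: float = 5.24
    rt_log_sigma: float = 0.35
    alerting_gain_ms: float = 20.0
    orientation_gain_ms: float = 30.0
    slip_prob: float = 0.03
    slip_shift_ms: float = 2000.0
    slip_log_mu: float = 6.0
    slip_log_sigma: float = 0.5
    # --- movement detection ---
    movement_shift_ms: float = 400.0
    movement_log_mu: float = 6.35
    movement_log_sigma: float = 0.4
    movement_p_correct: float = 0.92
    # --- spatial memory: log error ~ N(base + slope*n, sigma) ---
    mem_log_base: float = 2.30
    mem_decay_slope: float = 0.12
    mem_last_advantage: float = 0.25
    mem_log_sigma: float = 0.45
    # --- within-session learning, amplitude * exp(-rate * trial) ---
    #: task -> (amplitude, rate); visual/memory amplitudes are in log
    #: units, attention/movement in ms
    learning: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "visual": (0.25, 0.08),
            "attention": (60.0, 0.08),
            "movement": (120.0, 0.08),
            "memory": (0.30, 0.10),
        }
    )
    age: float = REFERENCE_AGE

    def __post_init__(self) -> None:
        for sub, g in self.guess_rates.items():
            if not 0 < g < 1:
                raise InvalidArgumentError(f"guess rate for {sub} must be in (0,1)")
        if not 0 <= self.lapse_rate < 0.1:
            raise InvalidArgumentError("lapse rate must be in [0, 0.1)")
        if not 0 <= self.slip_prob <= 0.2:
            raise InvalidArgumentError("slip probability must be in [0, 0.2]")
        if any(v <= 0 for v in self.thresholds_ms.values()):
            raise InvalidArgumentError("thresholds must be positive")

    def learning_term(self, task: str, trial_number: int | None) -> float:
        if trial_number is None or task not in self.learning:
            return 0.0
        amp, rate = self.learning[task]
        return amp * math.exp(-rate * trial_number)


def p_correct(
    profile: ObserverProfile,
    subtask: str,
    duration_ms: float,
    trial_number: int | None = None,
) -> float:
    """Probability of a correct answer at a given exposure duration.

    ``gamma + (1 - gamma - lambda) * L((ln t - ln theta_t) / sigma)`` with
    L the logistic function; at the threshold the non-guess component is
    at half height.  When ``trial_number`` is given, the effective
    threshold carries the (decaying) learning handicap of early trials.
    """
    if duration_ms <= 0:
        raise InvalidArgumentError("duration must be positive")
    gamma = profile.guess_rates[subtask]
    lam = profile.lapse_rate
    log_theta = math.log(profile.thresholds_ms[subtask]) + profile.learning_term(
        "visual", trial_number
    )
    z = (math.log(duration_ms) - log_theta) / profile.slope_sigma
    return float(gamma + (1.0 - gamma - lam) * expit(z))


def simulate_rt(
    profile: ObserverProfile,
    condition: str,
    trial_number: int,
    rng: np.random.Generator,
) -> float:
    """Draw one response time (ms) for the attention or movement task.

    Shifted log-normal baseline, minus the cueing gain (orientation or
    alerting; none for the neutral condition or movement contexts), plus
    the decaying learning handicap, replaced by a long slip RT with the
    profile's slip probability.
    """
    if condition in ATTENTION_CONDITIONS:
        base = profile.rt_shift_ms + rng.lognormal(
            profile.rt_log_mu, profile.rt_log_sigma
        )
        gain = {
            "neutral": 0.0,
            "alerting": profile.alerting_gain_ms,
            "orientation": profile.orientation_gain_ms,
        }[condition]
        learn = profile.learning_term("attention", trial_number)
    elif condition in MOVEMENT_CONDITIONS:
        base = profile.movement_shift_ms + rng.lognormal(
            profile.movement_log_mu, profile.movement_log_sigma
        )
        gain = 0.0
        learn = profile.learning_term("movement", trial_number)
    else:
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    if rng.random() < profile.slip_prob:
        return profile.slip_shift_ms + rng.lognormal(
            profile.slip_log_mu, profile.slip_log_sigma
        )
    return max(base - gain + learn, 1.0)


def simulate_memory_trial(
    profile: ObserverProfile,
    n_crosses: int,
    rng: np.random.Generator,
    trial_number: int | None = None,
) -> tuple[float, float]:
    """Localization errors (mm) for the first and last cue of one series.

    Log-normal errors; the first cue's log-mean grows linearly with the
    number of intervening crosses (memory decay), the last cue enjoys a
    fixed recency advantage and no set-size dependence.
    """
    if not 2 <= n_crosses <= 7:
        raise InvalidArgumentError(f"n_crosses must be in [2, 7], got {n_crosses}")
    learn = profile.learning_term("memory", trial_number)
    mu_first = profile.mem_log_base + profile.mem_decay_slope * n_crosses + learn
    mu_last = profile.mem_log_base - profile.mem_last_advantage + learn
    err_first = float(np.exp(rng.normal(mu_first, profile.mem_log_sigma)))
    err_last = float(np.exp(rng.normal(mu_last, profile.mem_log_sigma)))
    return err_first, err_last


@dataclass(frozen=True)
class SessionConfig:
    """Protocol constants of a battery run."""

    frame_ms: float = 1000.0 / 60.0
    start_index: int = 9
    min_visual_trials: int = 60
    max_visual_trials: int = 600
    single_subtask: str | None = None
    n_rt_per_condition: int = 32
    n_movement_correct: int = 40
    n_memory_trials: int = 30
    viewing_distance_mm: float = 600.0


def _profile_dict(profile: ObserverProfile) -> dict:
    d = {
        "thresholds_ms": dict(profile.thresholds_ms),
        "slope_sigma": profile.slope_sigma,
        "guess_rates": dict(profile.guess_rates),
        "lapse_rate": profile.lapse_rate,
        "rt_shift_ms": profile.rt_shift_ms,
        "rt_log_mu": profile.rt_log_mu,
        "rt_log_sigma": profile.rt_log_sigma,
        "alerting_gain_ms": profile.alerting_gain_ms,
        "orientation_gain_ms": profile.orientation_gain_ms,
        "slip_prob": profile.slip_prob,
        "movement_shift_ms": profile.movement_shift_ms,
        "movement_log_mu": profile.movement_log_mu,
        "movement_log_sigma": profile.movement_log_sigma,
        "movement_p_correct": profile.movement_p_correct,
        "mem_log_base": profile.mem_log_base,
        "mem_decay_slope": profile.mem_decay_slope,
        "mem_last_advantage": profile.mem_last_advantage,
        "mem_log_sigma": profile.mem_log_sigma,
        "learning": {k: list(v) for k, v in profile.learning.items()},
        "age": profile.age,
    }
    return d


def simulate_session(
    profile: ObserverProfile,
    seed: int,
    config: SessionConfig | None = None,
    session_id: str | None = None,
) -> SessionRecord:
    """Simulate one complete battery run for a profile.

    Tasks run in the fixed protocol order.  Each task draws from its own
    substream spawned from ``seed``, so the record is a pure function of
    (profile, seed).
    """
    cfg = config or SessionConfig()
    ss = np.random.SeedSequence(seed)
    rng_visual, rng_attention, rng_movement, rng_memory = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    ladder = build_ladder(cfg.frame_ms)

    # Task 1: interleaved staircase against the psychometric functions
    def responder(subtask: str, duration_ms: float, trial: int) -> bool:
        return bool(
            rng_visual.random() < p_correct(profile, subtask, duration_ms, trial)
        )

    states = run_visual_task(
        responder,
        ladder=ladder,
        rng=rng_visual,
        start_index=cfg.start_index,
        min_trials=cfg.min_visual_trials,
        max_trials=cfg.max_visual_trials,
        single_subtask=cfg.single_subtask,
    )
    visual_rows = [
        VisualTrialRow(
            trial_number=t,
            subtask=sub,
            ladder_index=idx,
            duration_ms=ladder.duration(idx),
            correct=c,
        )
        for sub, st in states.items()
        for (t, idx, c) in st.history
    ]
    visual_rows.sort(key=lambda r: r.trial_number)

    # Task 2: 32 RTs per cueing condition in shuffled order
    conditions = np.repeat(ATTENTION_CONDITIONS, cfg.n_rt_per_condition)
    rng_attention.shuffle(conditions)
    attention_rows = [
        RTTrialRow(
            task="attention",
            trial_number=i + 1,
            condition=str(cond),
            rt_ms=simulate_rt(profile, str(cond), i + 1, rng_attention),
        )
        for i, cond in enumerate(conditions)
    ]

    # Task 3: trials until the required number of correct answers
    movement_rows: list[RTTrialRow] = []
    n_correct = 0
    t = 0
    while n_correct < cfg.n_movement_correct:
        t += 1
        cond = MOVEMENT_CONDITIONS[int(rng_movement.integers(0, 2))]
        correct = bool(rng_movement.random() < profile.movement_p_correct)
        rt = simulate_rt(profile, cond, t, rng_movement)
        movement_rows.append(
            RTTrialRow(
                task="movement",
                trial_number=t,
                condition=cond,
                rt_ms=rt,
                correct=correct,
            )
        )
        n_correct += correct

    # Task 4: fixed number of memory series, random set sizes
    memory_rows = []
    for i in range(1, cfg.n_memory_trials + 1):
        n_crosses = int(rng_memory.integers(2, 8))
        err_first, err_last = simulate_memory_trial(
            profile, n_crosses, rng_memory, trial_number=i
        )
        memory_rows.append(
            MemoryTrialRow(
                trial_number=i,
                n_crosses=n_crosses,
                err_first_mm=err_first,
                err_last_mm=err_last,
            )
        )

    return SessionRecord(
        session_id=session_id or f"sim-{seed}",
        seed=seed,
        profile=_profile_dict(profile),
        environment=EnvironmentBlock(
            frame_ms=ladder.frame_ms,
            viewing_distance_mm=cfg.viewing_distance_mm,
        ),
        visual_trials=visual_rows,
        attention_trials=attention_rows,
        movement_trials=movement_rows,
        memory_trials=memory_rows,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Age-structured cohort of simulated participants.

    Age gradients are per-year shifts applied to the generative
    parameters relative to the reference age of 75; dispersions combine a
    common 'processing speed' factor shared across tasks with
    task-specific noise.  The default calibration makes the composite
    score decline by roughly 0.5 points per year of age.
    """

    n: int = 100
    age_min: float = 65.0
    age_max: float = 90.0
    seed: int = 0
    #: per-year multiplicative shift of the log thresholds
    grad_log_threshold: float = 0.02
    #: per-year additive shift of attention RTs (ms)
    grad_rt_ms: float = 2.0
    #: per-year additive shift of movement RTs (ms)
    grad_movement_ms: float = 8.0
    #: per-year additive shift of the log localization error
    grad_mem_log: float = 0.0125
    #: common-factor and idiosyncratic between-subject dispersions
    sd_common: float = 1.0
    sd_log_threshold: tuple[float, float] = (0.35, 0.15)
    sd_rt_ms: tuple[float, float] = (25.0, 15.0)
    sd_movement_ms: tuple[float, float] = (90.0, 50.0)
    sd_mem_log: tuple[float, float] = (0.30, 0.12)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidArgumentError("cohort size must be >= 1")


def sample_profile(
    spec: CohortSpec, age: float, rng: np.random.Generator
) -> ObserverProfile:
    """Draw one observer profile at a given age under the cohort model."""
    base = ObserverProfile()
    da = age - REFERENCE_AGE
    g = rng.normal(0.0, spec.sd_common)

    def shift(gradient: float, sds: tuple[float, float]) -> float:
        return gradient * da + sds[0] * g + sds[1] * rng.normal()

    thresholds = {
        sub: base.thresholds_ms[sub]
        * math.exp(shift(spec.grad_log_threshold, spec.sd_log_threshold))
        for sub in SUBTASKS
    }
    return replace(
        base,
        age=float(age),
        thresholds_ms=thresholds,
        rt_shift_ms=max(base.rt_shift_ms + shift(spec.grad_rt_ms, spec.sd_rt_ms), 50.0),
        movement_shift_ms=max(
            base.movement_shift_ms + shift(spec.grad_movement_ms, spec.sd_movement_ms),
            100.0,
        ),
        mem_log_base=base.mem_log_base + shift(spec.grad_mem_log, spec.sd_mem_log),
    )


def generate_cohort(
    spec: CohortSpec, config: SessionConfig | None = None
) -> list[tuple[ObserverProfile, SessionRecord]]:
    """Sample ``spec.n`` participants and simulate one session each.

    Ages are uniform over the spec's range.  Each participant's profile
    and session seed derive from a spawned substream of the cohort seed,
    so the cohort is a pure function of the spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    out: list[tuple[ObserverProfile, SessionRecord]] = []
    for i, child in enumerate(ss.spawn(spec.n)):
        rng = np.random.default_rng(child)
        age = float(rng.uniform(spec.age_min, spec.age_max))
        profile = sample_profile(spec, age, rng)
        # a fresh staircase seed is drawn if the observer's run hits the
        # trial cap; the profile itself is kept
        record = None
        for _ in range(3):
            session_seed = int(rng.integers(0, 2**31 - 1))
            try:
                record = simulate_session(
                    profile, session_seed, config,
                    session_id=f"cohort-{spec.seed}-{i:04d}",
                )
                break
            except NonConvergenceError:
                continue
        if record is None:
            raise NonConvergenceError(
                f"participant {i} failed to converge in 3 staircase runs"
            )
        out.append((profile, record))
    return out
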
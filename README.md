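# meddrive

A scoring engine and virtual-participant simulator for **MedDrive**, a
computer-based neuropsychological battery that measures age-related decline
in visual processing speed in older drivers. The package implements the
battery's computational core — the adaptive exposure-duration staircase,
trial-level scoring with slip removal and learning-effect adjustment, the
published score transformations and 0–100 composite, and test–retest
reliability statistics — together with a generative observer model, so that
every part of the pipeline can be exercised and validated on simulated
participants without access to human data.

It is written for researchers in psychometrics, traffic medicine, and
cognitive aging who need a transparent, reproducible implementation of the
battery's scoring rules, or a simulation harness for studying the
statistical behavior of adaptive staircases and composite cognitive scores.

## The battery in brief

Four tasks produce seven raw outcomes:

1. **Visual recognition.** Three interleaved subtasks (central, peripheral,
   dual) share a frame-quantized ladder of exposure durations
   (16.7–4633.3 ms at 60 Hz). Each subtask runs a one-up/one-down
   staircase: correct → one step shorter, wrong → one step longer. The task
   may end only after 60 stimuli, once each subtask shows ≥ 3 upper and
   ≥ 3 lower reversals whose last three of each kind span ≤ 3 consecutive
   rungs. The outcome per subtask is the geometric mean of the
   learning-adjusted exposure durations after the first reversal — an
   estimate of the 50% threshold *θ* of the psychometric function
   *p(t) = γ + (1 − γ − λ)·L((ln t − ln θ)/σ)*.
2. **Central cue attention.** 32 response times per cueing condition
   (neutral, alerting, orientation); per condition the 3 slowest are
   removed, an OLS learning trend on ln(trial) is regressed out, and the
   adjusted means give the condition RTs and the cueing gains
   (neutral − cued).
3. **Movement detection.** Trials until 40 correct; the 4 slowest are
   removed and the learning-adjusted mean RT is the outcome.
4. **Spatial working memory.** 30 series of 2–7 crosses; localization
   errors for first and last cue are trimmed (3 worst), log-transformed,
   learning-adjusted, and summarized as geometric means (mm), plus the
   memory-decay slope of log first-cue error on set size.

Each outcome *x* maps onto a score in [0, 1] via the published calibration
(`1 − (ln x − a)/b` for thresholds, `1 − (x − a)/b` for RTs and distances),
and the composite is 100 × the weighted mean of the seven scores (equal
weights by default; one-factor loadings optionally).

## Worked example

```bash
python examples/score_session.py
```

```
raw outcomes
  central / peripheral / dual thresholds: 230 / 243 / 2301 ms
  orientation-cue RT 347 ms (orientation gain 32, alerting gain 34 ms)
  movement detection RT 1111 ms
  memory error first/last cue 15.7 / 9.0 mm, decay slope 0.113 log-mm per cross
scores [0-100], higher = better
          central:  26.9
       peripheral:  30.9
             dual:   7.9
  orientation_cue:  43.6
         movement:  45.9
     memory_first:  49.2
      memory_last:  72.4
  composite: 39.6
```

The simulated observer's true central threshold is 230 ms and the staircase
recovers 230 ms; a composite near 40 is typical of drivers in their
mid-seventies, while young adults average around 65. The other examples
cover the staircase vs. its Markov-chain oracle (`run_staircase.py`),
cross-sectional aging in a simulated cohort (`cohort_aging.py`, ≈ −5
composite points per decade under the default calibration), test–retest
reliability via ICC(3,1) (`reliability_icc.py`), and data-driven composite
weights from a one-factor model (`factor_weights.py`).

A thin CLI wraps the same functions:

```bash
meddrive simulate-cohort --n 10 --seed 1 --out cohort/
meddrive score-session cohort/cohort-1-0000.json
meddrive icc wide.csv
```

## Layout

- `src/meddrive/ladder.py`, `staircase.py` — exposure ladder and staircase engine
- `src/meddrive/scoring.py` — trial scoring (trimming, learning adjustment, outcomes)
- `src/meddrive/transform.py` — score transformations, composite, on-road categories
- `src/meddrive/simulate.py` — observer profiles, session and cohort simulation
- `src/meddrive/stats.py` — ICC(3,1), staircase stationary-distribution oracle, one-factor fit
- `src/meddrive/session.py`, `pipeline.py`, `cli.py` — session records, end-to-end scoring, CLI
- `docs/methods.md` — model assumptions, parameter choices, and limitations
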
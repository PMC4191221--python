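# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the battery's written description leaves
the design open.

## Staircase engine

**Ladder.** The exposure ladder is the frame-count pattern
1, 2, 3, 4, 5, 7, 9, 13, 17, 22, 29, 39, 51, 68, 90, 119, 158, 210, 278
multiplied by the display frame period and reported to 0.1 ms. The
conventional shorthand period "16.7 ms" does not reproduce the canonical
duration list by literal multiplication (2 × 16.7 = 33.4, not 33.3), so
`build_ladder` snaps the requested period to the nearest integer refresh
rate when within 2% of one — 16.7 ms resolves to the exact 60 Hz period,
8.3 ms to 120 Hz. The rungs are close to log-spaced (log-gaps 0.69 at the
bottom shrinking to ≈ 0.28 above 150 ms), which is what makes the
geometric-mean estimator sensible.

**Reversals.** The battery's description never defines a reversal. We use
the standard transformed up-down convention: an upper reversal is a local
maximum of the presented-index path (movement switches up→down), a lower
reversal a local minimum. A plateau produced by clamping at a ladder bound
counts once, attributed to the first clamped trial — without this, an
observer pinned at the fastest rung would accumulate spurious reversals. A
direction change implied by the final response of a session registers only
when a subsequent stimulus is presented; in practice one always is,
because the termination check runs after every trial.

**Termination.** The rule "three upper and three lower reversals within
three consecutive values" is evaluated on the *most recent* three of each
kind, requiring their ladder indices to span ≤ 3 adjacent rungs, and never
before 60 total stimuli. Using the most recent reversals implements the
intent of detecting stabilization around a central point; older, wider
reversals from the burn-in phase do not block termination.

**Trial cap.** Runs are capped at 600 stimuli, after which a
non-convergence error is raised. With the default observer model ~2.5% of
typical runs exceed 300 stimuli (the rule demands simultaneous stability
of all three interleaved staircases) but none of 150 exceeded 600; the cap
exists to guarantee termination on pathological response patterns, e.g.
pure guessing. Cohort generation redraws the staircase seed up to three
times for a participant whose run hits the cap, keeping the profile.

**Start.** Staircases start mid-ladder (index 9, 366.7 ms at 60 Hz),
minimizing burn-in for typical observers. Configurable.

**Threshold estimator.** Trials strictly after the subtask's first
reversal are log-transformed, the learning trend (OLS of log-duration on
log trial number) is removed with the series re-anchored at the last
trial, and the mean log is exponentiated. The learning trend is fitted by
default on *all* trials of the subtask — the pre-reversal descent carries
most of the information about early-session learning — with a `post` mode
restricting the fit to the averaged trials.

## Trial scoring

**Worst-measure removal** drops the k largest values (slowest RTs, largest
errors); ties drop the later trial, keeping the rule deterministic.
Removal precedes the learning fit throughout.

**Learning adjustment** is OLS of the value on ln(trial number); adjusted
values are residuals plus the fitted value at the anchor (default: the
last trial), so a scored outcome reflects end-of-session, i.e. trained,
performance, and constant series are left exactly unchanged.

**Attention task.** The three slowest measures are removed per condition
(the operative task description; a `pooled_two_slowest` switch implements
the variant that drops only the two slowest of the whole 96-trial block).
The learning regressor is the session-wide trial index; each condition is
anchored at the session's final trial so the three condition means are
comparable. Gains are identically neutral mean − cued mean.

**Movement task.** The first 40 correct trials enter; the 4 slowest are
removed; the learning fit uses the first 30 *retained* measures indexed by
retained order (1…30), and all 36 retained measures are adjusted to the
final retained index.

**Memory task.** Per cue: 3 worst removed, log-transform, learning
adjustment, exponentiated mean (a geometric mean in mm, matching the
multiplicative error structure). The decay slope is OLS of retained log
first-cue error on set size; it is flagged undefined if all retained
series share one set size. Trimming the largest errors slightly attenuates
the slope relative to the generative value (large errors are more likely
at high set sizes); validation therefore compares against a Monte-Carlo
oracle of the trimmed definition rather than the raw parameter.

## Score transformations and composite

Constants are stored exactly as published (offsets 2.833; scales 3.564,
3.852, 5.328 on log-thresholds; 150/350, 300/1500, 1/29 on the linear
maps) and are not re-derived. Scores are clipped to [0, 1] *before*
weighting — values outside the retained ranges would otherwise leave the
scale — and the composite is 100 × the weighted mean. Default weights are
equal (1/7); `fit_one_factor` loadings can be plugged in where a
data-driven weighting is wanted. Inverse transforms are exact on [0, 1]
and are how the retained-range endpoints are verified.

## Observer model

The simulator generates the statistical structure the scoring assumes,
with defaults describing a typical driver in their mid-seventies (scores
near the middle of the retained ranges, composite ≈ 40):

- **Psychometric functions**: logistic in log-duration; width σ = 0.125
  (slope 8 per log-unit); guess rates 1/5 (central, five stimulus
  alternatives), 1/6 (peripheral, six arrows), 1/30 (dual — both judgments
  must be right); lapse rate 0.02. Thresholds 230 / 280 / 1800 ms.
- **Response times**: shifted log-normal (attention: 180 ms shift,
  log-mean 5.24, log-SD 0.35 → mean ≈ 380 ms; movement: 400 ms shift,
  log-mean 6.35, log-SD 0.4 → mean ≈ 1020 ms), minus a 20 ms alerting or
  30 ms orientation gain, contaminated by slips (probability 0.03, RT
  2000 ms plus a log-normal tail) mirroring the too-soft keypress repeated
  after 1–2 s.
- **Memory errors**: log-normal; first-cue log-mean 2.30 + 0.12 per cross,
  last cue 0.25 log-units lower (recency), log-SD 0.45.
- **Learning**: amplitude · exp(−rate · trial) per task — deliberately a
  different functional form from the ln-trial regression the scoring uses,
  so the tests also exercise the adjustment's robustness to model
  mismatch.

**Cohorts.** Age acts on thresholds (log-gradient 0.02/yr), RT shifts
(2 ms/yr attention, 8 ms/yr movement), and memory log-error (0.0125/yr) —
a processing-speed account; guess and lapse rates are age-invariant.
These gradients were chosen analytically: propagated through the score
transformations they sum to ≈ −0.051 composite points per year, i.e. the
≈ 5-points-per-decade cross-sectional decline the battery reports, which a
300-participant simulated cohort reproduces (−5.1/decade, mean composite
≈ 41, SD ≈ 9). Between-subject dispersion combines a common
processing-speed factor with task-specific noise; the published data
constrain only the composite SD (≈ 12), so the split is a calibration
choice, not an empirical fact.

**What the simulator does not emulate**: day-to-day observer state
(fatigue, practice carry-over across sessions), response-strategy shifts,
congruent/incongruent movement-context effects, eye movements, hardware
timing jitter. Simulated test–retest reliability is therefore optimistic —
repeated sessions differ only by measurement noise, so ICC(3,1) on
simulated panels (~0.96) exceeds the ~0.85 observed with humans, and
passing recovery tests demonstrate correctness of the scoring rules, not
human-level reliability.

## Statistics

**ICC(3,1)** is computed from the two-way mean squares,
(BMS − EMS)/(BMS + (k−1)·EMS), with the Shrout–Fleiss F-based 95%
interval. Sessions are fixed effects, so a constant per-session practice
shift does not lower the coefficient; per-session means are reported
alongside rather than removed. A zero residual mean square returns ICC 1
with a degenerate interval. The implementation is cross-checked against
pingouin's ICC3 in the tests.

**Staircase oracle.** The one-up/one-down staircase is a birth–death
chain on ladder indices (down with p_correct, up otherwise, clamped
ends); its stationary distribution is the unit-eigenvalue left
eigenvector of the 19×19 transition matrix. The stationary mean
log-duration is the quantity the geometric-mean estimator converges to
for a stationary observer, and serves as the independent oracle in
validation: over 20 observers with thresholds log-uniform in
[30, 1000] ms, estimates from 300-trial runs stay within one local
ladder-step log-width of the oracle mean.

**One-factor model.** Iterated principal factoring on the correlation
matrix (communalities initialized from squared multiple correlations,
leading-eigenvector updates, tolerance 1e-6, ≤ 500 iterations; Heywood
communalities clamped at 0.999 and flagged; first loading sign-normalized
non-negative). This flat single factor replaces a hierarchical structural
model and is offered only for optional composite weights. With
independent inputs the fitted loadings reflect sampling correlations of
order √(p/n) — at n = 2000, p = 7 individual null loadings can reach
≈ 0.25 even though the explained common variance stays near zero, which
is how the null case is validated.

## Numerical and I/O choices

Learning fits use `np.polyfit` on ln(trial); degenerate designs (fewer
than 3 points, or a single distinct trial number) raise typed errors
rather than returning NaN. Session records are canonical JSON — sorted
keys, floats at 6 significant digits — so byte-identity is the
determinism check. All simulation randomness flows through named
`SeedSequence` substreams per task, making every record a pure function
of (profile, seed).

## Problem sizes used in validation

Module tests run exhaustive reversal checks to sequence length 10 (1024
patterns), 200-trial staircases for threshold recovery (60 observers),
and 10,000-trial runs for the stationarity check. The acceptance-style
checks use 20 observers × 300 trials for oracle equivalence, 100 sessions
for parameter recovery, a 500 × 5 matrix for the ICC variance-component
check, and a 300-participant cohort for the aging gradient.
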
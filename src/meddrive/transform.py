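"""Score transformations, the 0-100 composite, and the on-road categories.

Each raw outcome is mapped onto a [0, 1] score that is 1 at the best end
of its retained range and 0 at the worst end.  Exposure-duration
thresholds use a log-linear map ``1 - (ln t - offset)/scale`` (their
retained ranges are log-wide); response times and localization errors use
a linear map ``1 - (x - offset)/scale``.  The transformation constants
are the instrument's published calibration, derived from the 10th-90th
percentile envelope of younger and older drivers, and are stored exactly
as printed.  The composite is 100 times the weighted mean of the seven
scores (equal weights by default), 0 meaning poor performance on every
task and 100 optimal performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError

ONROAD_CATEGORIES = ("excellent", "good", "moderate", "poor")


@dataclass(frozen=True)
class TransformSpec:
    """One outcome's score transformation.

    ``kind`` is "log" (offset/scale apply to ln of the raw value, in ms)
    or "linear" (raw ms or mm).  ``retained_range`` is the (best, worst)
    span of raw values the transformation maps onto [1, 0].
    """

    outcome_name: str
    kind: str  # "log" | "linear"
    offset: float
    scale: float
    retained_range: tuple[float, float]
    units: str

    def score(self, raw_value: float, clip: bool = True) -> float:
        if self.kind == "log":
            if raw_value <= 0:
                raise InvalidArgumentError(
                    f"{self.outcome_name}: raw value must be positive for a "
                    f"log transform, got {raw_value}"
                )
            s = 1.0 - (math.log(raw_value) - self.offset) / self.scale
        else:
            s = 1.0 - (raw_value - self.offset) / self.scale
        return min(max(s, 0.0), 1.0) if clip else s

    def invert(self, score: float) -> float:
        if not 0.0 <= score <= 1.0:
            raise InvalidArgumentError(f"score must be in [0, 1], got {score}")
        x = self.offset + (1.0 - score) * self.scale
        return math.exp(x) if self.kind == "log" else x


#: The seven scored outcomes, keyed by short name, in canonical order.
TRANSFORMS: Mapping[str, TransformSpec] = {
    "central": TransformSpec(
        "central", "log", 2.833, 3.564, (17.0, 600.0), "ms"
    ),
    "peripheral": TransformSpec(
        "peripheral", "log", 2.833, 3.852, (17.0, 800.0), "ms"
    ),
    "dual": TransformSpec(
        "dual", "log", 2.833, 5.328, (17.0, 3500.0), "ms"
    ),
    "orientation_cue": TransformSpec(
        "orientation_cue", "linear", 150.0, 350.0, (150.0, 500.0), "ms"
    ),
    "movement": TransformSpec(
        "movement", "linear", 300.0, 1500.0, (300.0, 1800.0), "ms"
    ),
    "memory_first": TransformSpec(
        "memory_first", "linear", 1.0, 29.0, (1.0, 30.0), "mm"
    ),
    "memory_last": TransformSpec(
        "memory_last", "linear", 1.0, 29.0, (1.0, 30.0), "mm"
    ),
}

SCORE_NAMES: tuple[str, ...] = tuple(TRANSFORMS)


@dataclass(frozen=True)
class ScoreVector:
    """Seven [0, 1] scores and the 0-100 composite."""

    scores: dict[str, float]
    composite: float
    weights: dict[str, float]


def transform(outcome_name: str, raw_value: float) -> float:
    """[0, 1] score for a named raw outcome (clipped)."""
    spec = TRANSFORMS.get(outcome_name)
    if spec is None:
        raise InvalidArgumentError(
            f"unknown outcome {outcome_name!r}; known: {list(TRANSFORMS)}"
        )
    return spec.score(raw_value)


def invert_transform(outcome_name: str, score: float) -> float:
    """Raw value whose (unclipped) transform equals ``score``."""
    spec = TRANSFORMS.get(outcome_name)
    if spec is None:
        raise InvalidArgumentError(f"unknown outcome {outcome_name!r}")
    return spec.invert(score)


def composite(
    scores: Sequence[float] | Mapping[str, float],
    weights: Sequence[float] | Mapping[str, float] | None = None,
) -> float:
    """0-100 composite: 100 x the weighted mean of the seven scores.

    Scores are clipped to [0, 1] before weighting.  Weights must be
    non-negative and are normalized to sum to 1; by default every score
    carries weight 1/7.  Alternative weights (e.g. one-factor loadings
    from :func:`meddrive.stats.fit_one_factor`) may be supplied.
    """
    if isinstance(scores, Mapping):
        scores = [scores[name] for name in SCORE_NAMES]
    s = np.asarray(scores, dtype=float)
    if s.shape != (len(SCORE_NAMES),):
        raise InvalidArgumentError(
            f"expected {len(SCORE_NAMES)} scores, got shape {s.shape}"
        )
    if weights is None:
        w = np.full(len(SCORE_NAMES), 1.0 / len(SCORE_NAMES))
    else:
        if isinstance(weights, Mapping):
            weights = [weights[name] for name in SCORE_NAMES]
        w = np.asarray(weights, dtype=float)
        if w.shape != s.shape:
            raise InvalidArgumentError("weights must match the score count")
        if np.any(w < 0):
            raise InvalidArgumentError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise InvalidArgumentError("weights must not all be zero")
        w = w / total
    s = np.clip(s, 0.0, 1.0)
    return float(100.0 * (w * s).sum())


def score_outcomes(
    outcomes: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> ScoreVector:
    """Transform a full set of raw outcomes and build the composite.

    ``outcomes`` maps the seven canonical score names to raw values
    (thresholds and RTs in ms, localization errors in mm).
    """
    scores = {name: transform(name, outcomes[name]) for name in SCORE_NAMES}
    if weights is None:
        weights = {name: 1.0 / len(SCORE_NAMES) for name in SCORE_NAMES}
    comp = composite(scores, weights)
    return ScoreVector(scores=scores, composite=comp, weights=dict(weights))


def classify_onroad(lapse_count: int) -> str:
    """Map an on-road lapse count (0-8 checklist items) to its category:
    0 lapses = excellent, 1-2 = good, 3-5 = moderate, 6-8 = poor."""
    if not isinstance(lapse_count, (int, np.integer)):
        raise InvalidArgumentError("lapse_count must be an integer")
    if lapse_count < 0 or lapse_count > 8:
        raise InvalidArgumentError(
            f"lapse_count must be in [0, 8], got {lapse_count}"
        )
    if lapse_count == 0:
        return "excellent"
    if lapse_count <= 2:
        return "good"
    if lapse_count <= 5:
        return "moderate"
    return "poor"
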
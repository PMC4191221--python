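"""Reliability and measurement-model statistics.

Three tools: the two-way mixed, single-measure intraclass correlation
ICC(3,1) used for test-retest reliability; the exact stationary
distribution of the one-up/one-down staircase viewed as a birth-death
Markov chain on the ladder (an independent oracle for the threshold
estimator); and a single-factor loading estimator that supplies optional
composite weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidArgumentError
from .ladder import DurationLadder


# ---------------------------------------------------------------------------
# ICC(3,1)


@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed single-measure intraclass correlation.

    ``var_between`` / ``var_residual`` are the implied variance
    components; the population value of the coefficient is
    var_between / (var_between + var_residual).
    """

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_sessions: int
    var_between: float
    var_residual: float


def icc_3_1(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1) with its F-based confidence interval.

    Sessions (columns) are treated as fixed effects, so a constant
    per-session shift (e.g. residual practice) does not penalize the
    coefficient.  With between-subject mean square BMS and residual mean
    square EMS over k sessions::

        ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

    The 95% interval follows Shrout & Fleiss' F-distribution bounds.

    Parameters
    ----------
    matrix : (n_subjects, n_sessions) array
        Complete score matrix, one row per subject.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InvalidArgumentError("matrix must be 2-D (subjects x sessions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InvalidArgumentError(
            f"need >= 2 subjects and >= 2 sessions, got {n} x {k}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("matrix contains missing or non-finite cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if ems <= 0:  # zero residual variance: perfect reliability
        icc, ci_low, ci_high = 1.0, 1.0, 1.0
    else:
        icc = (bms - ems) / (bms + (k - 1) * ems)
        f_obs = bms / ems
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(min(ci_high, 1.0)),
        n_subjects=n,
        n_sessions=k,
        var_between=float(max((bms - ems) / k, 0.0)),
        var_residual=float(ems),
    )


# ---------------------------------------------------------------------------
# staircase stationary distribution


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run occupancy of the staircase over ladder indices."""

    probs: np.ndarray
    mean_log_duration: float

    @property
    def mean_duration_ms(self) -> float:
        return float(np.exp(self.mean_log_duration))


def staircase_stationary_distribution(
    p_correct_by_index: np.ndarray, ladder: DurationLadder
) -> StationaryDistribution:
    """Stationary distribution of the one-up/one-down staircase chain.

    The staircase is a birth-death chain on ladder indices: from index i
    it moves down with probability ``p_correct[i]`` and up with the
    complement, clamped (self-loop) at both ends.  The stationary vector
    is the unit-eigenvalue left eigenvector of the transition matrix; its
    mean log-duration is the quantity the geometric-mean threshold
    estimator converges to for a stationary observer.
    """
    p = np.asarray(p_correct_by_index, dtype=float)
    m = len(ladder)
    if p.shape != (m,):
        raise InvalidArgumentError(
            f"need one probability per ladder index ({m}), got shape {p.shape}"
        )
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("probabilities must lie in [0, 1]")
    P = np.zeros((m, m))
    for i in range(m):
        down = max(i - 1, 0)
        up = min(i + 1, m - 1)
        P[i, down] += p[i]
        P[i, up] += 1.0 - p[i]
    vals, vecs = np.linalg.eig(P.T)
    j = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, j])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    mean_log = float(np.dot(pi, np.asarray(ladder.log_durations)))
    return StationaryDistribution(probs=pi, mean_log_duration=mean_log)


# ---------------------------------------------------------------------------
# one-factor model


@dataclass(frozen=True)
class FactorSolution:
    """Single-factor solution on standardized scores.

    ``weights`` are the positive loadings normalized to sum to one,
    usable as composite weights.  ``converged`` / ``heywood`` flag
    estimation problems.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    weights: np.ndarray
    converged: bool
    heywood: bool
    n_iter: int


def fit_one_factor(
    score_matrix: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FactorSolution:
    """Iterated principal-factor estimate of a single common factor.

    Operates on the correlation matrix of the columns: communalities are
    initialized from squared multiple correlations, the reduced matrix's
    leading eigenvector gives the loadings, and communalities are updated
    until the largest change falls below ``tol``.  Loadings are
    sign-normalized so the first is non-negative.  Communalities reaching
    1 (a Heywood case) are clamped and flagged.
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InvalidArgumentError("score matrix needs >= 3 columns")
    n, p = x.shape
    if n < 5 * p:
        raise InvalidArgumentError(
            f"need at least {5 * p} rows for {p} columns, got {n}"
        )
    r = np.corrcoef(x, rowvar=False)
    try:
        h = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    except np.linalg.LinAlgError:
        h = np.full(p, 0.5)
    h = np.clip(h, 0.0, 0.999)
    heywood = False
    converged = False
    loadings = np.zeros(p)
    it = 0
    for it in range(1, max_iter + 1):
        rr = r.copy()
        np.fill_diagonal(rr, h)
        vals, vecs = np.linalg.eigh(rr)
        lam, v = vals[-1], vecs[:, -1]
        loadings = v * np.sqrt(max(lam, 0.0))
        h_new = loadings**2
        if np.any(h_new >= 1.0):
            heywood = True
            h_new = np.clip(h_new, 0.0, 0.999)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            converged = True
            break
        h = h_new
    if loadings[0] < 0:
        loadings = -loadings
    uniq = np.clip(1.0 - loadings**2, 0.0, 1.0)
    pos = np.clip(loadings, 0.0, None)
    weights = pos / pos.sum() if pos.sum() > 0 else np.full(p, 1.0 / p)
    return FactorSolution(
        loadings=loadings,
        uniquenesses=uniq,
        weights=weights,
        converged=converged,
        heywood=heywood,
        n_iter=it,
    )
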
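"""Parameter-derivation formulas for the dysphagia cost-utility models.

Everything the models consume as a transition probability, utility
distribution or schedule is derived here from published source data:
cumulative risks are converted to weekly incidence rates, 2x2 outcome
tables to relative risks with log-normal confidence intervals, printed
confidence intervals to standard deviations and Beta shapes for the
probabilistic sensitivity analysis, prevalence time points to a weekly
dysphagia-resolution schedule, and piecewise post-stroke mortality to a
weekly death-probability vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CalibrationError,
    InvalidInputError,
    InvalidVarianceError,
    UndefinedEstimateError,
)

__all__ = [
    "TwoByTwoCounts",
    "StudyRisk",
    "RREstimate",
    "PrevalencePoint",
    "ResolutionSchedule",
    "MortalitySchedule",
    "incidence_rate_from_cumulative",
    "cumulative_risk_from_rate",
    "pooled_incidence_rate",
    "pooled_incidence_rate_from_csv",
    "relative_risk",
    "weekly_probability",
    "sd_from_interval",
    "beta_from_moments",
    "lognormal_from_ci",
    "binomial_ci",
    "calibrate_resolution",
    "mortality_schedule",
    "fit_log_survival",
]

DAYS_PER_WEEK = 7
YEAR_DAYS = 365


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwoCounts:
    """Event counts in an exposed and a reference group.

    ``events_exposed`` out of ``n_exposed`` experienced the outcome in the
    exposed group, ``events_reference`` out of ``n_reference`` in the
    reference group.
    """

    events_exposed: int
    n_exposed: int
    events_reference: int
    n_reference: int

    def __post_init__(self) -> None:
        for label, events, n in (
            ("exposed", self.events_exposed, self.n_exposed),
            ("reference", self.events_reference, self.n_reference),
        ):
            if n <= 0:
                raise InvalidInputError(f"n_{label} must be positive, got {n}")
            if not 0 <= events <= n:
                raise InvalidInputError(
                    f"events_{label} must lie in [0, n_{label}], got {events}/{n}"
                )

    def swapped(self) -> "TwoByTwoCounts":
        """Exchange the exposed and reference groups."""
        return TwoByTwoCounts(
            self.events_reference, self.n_reference,
            self.events_exposed, self.n_exposed,
        )


@dataclass(frozen=True)
class StudyRisk:
    """Cumulative event risk observed in one study over a fixed follow-up."""

    cumulative_risk: float
    followup_weeks: float
    n_patients: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.cumulative_risk < 1.0:
            raise InvalidInputError(
                f"cumulative_risk must lie in [0, 1), got {self.cumulative_risk}"
            )
        if self.followup_weeks <= 0:
            raise InvalidInputError(
                f"followup_weeks must be positive, got {self.followup_weeks}"
            )
        if self.n_patients <= 0:
            raise InvalidInputError(
                f"n_patients must be positive, got {self.n_patients}"
            )


@dataclass(frozen=True)
class RREstimate:
    """Relative risk with a confidence interval on the ratio scale."""

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.reliable and not self.ci_low <= self.point <= self.ci_high:
            raise InvalidInputError(
                "confidence interval must contain the point estimate"
            )


@dataclass(frozen=True)
class PrevalencePoint:
    """Fraction of the cohort still dysphagic a given number of days post stroke."""

    time_days: int
    fraction_with_dysphagia: float

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise InvalidInputError("time_days must be non-negative")
        if not 0.0 <= self.fraction_with_dysphagia <= 1.0:
            raise InvalidInputError(
                f"fraction_with_dysphagia must lie in [0, 1], "
                f"got {self.fraction_with_dysphagia}"
            )


@dataclass(frozen=True)
class ResolutionSchedule:
    """Per-cycle probability that dysphagia resolves, one entry per model week."""

    weekly_resolution_prob: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.weekly_resolution_prob, dtype=float)
        object.__setattr__(self, "weekly_resolution_prob", probs)
        if probs.ndim != 1:
            raise InvalidInputError("resolution schedule must be a 1-D vector")
        if np.any((probs < 0) | (probs > 1)):
            raise InvalidInputError("resolution probabilities must lie in [0, 1]")

    @property
    def horizon_weeks(self) -> int:
        return len(self.weekly_resolution_prob)

    def prevalence(self) -> np.ndarray:
        """Dysphagia survival curve implied by the schedule (index 0 = week 0)."""
        return np.concatenate(
            ([1.0], np.cumprod(1.0 - self.weekly_resolution_prob))
        )


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-cycle probability of death, one entry per model week."""

    weekly_death_prob: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.weekly_death_prob, dtype=float)
        object.__setattr__(self, "weekly_death_prob", probs)
        if probs.ndim != 1:
            raise InvalidInputError("mortality schedule must be a 1-D vector")
        if np.any((probs < 0) | (probs > 1)):
            raise InvalidInputError("death probabilities must lie in [0, 1]")

    @property
    def horizon_weeks(self) -> int:
        return len(self.weekly_death_prob)

    def survival(self) -> np.ndarray:
        """Cumulative survival curve (index 0 = week 0, value 1.0)."""
        return np.concatenate(
            ([1.0], np.cumprod(1.0 - self.weekly_death_prob))
        )


# ---------------------------------------------------------------------------
# Rate conversions
# ---------------------------------------------------------------------------

def incidence_rate_from_cumulative(study: StudyRisk) -> float:
    """Weekly incidence rate from a cumulative risk over a follow-up.

    Assumes a constant hazard during follow-up, so the rate is
    ``-ln(1 - CR) / T`` with ``T`` in weeks.
    """
    return -math.log1p(-study.cumulative_risk) / study.followup_weeks


def cumulative_risk_from_rate(ir_weekly: float, followup_weeks: float) -> float:
    """Inverse of :func:`incidence_rate_from_cumulative`."""
    if ir_weekly < 0 or followup_weeks < 0:
        raise InvalidInputError("rate and follow-up must be non-negative")
    return -math.expm1(-ir_weekly * followup_weeks)


def pooled_incidence_rate(studies: Sequence[StudyRisk]) -> float:
    """Patient-weighted mean of per-study weekly incidence rates."""
    if not studies:
        raise InvalidInputError("pooled_incidence_rate requires at least one study")
    rates = np.array([incidence_rate_from_cumulative(s) for s in studies])
    weights = np.array([s.n_patients for s in studies], dtype=float)
    return float(np.average(rates, weights=weights))


def pooled_incidence_rate_from_csv(path) -> float:
    """Pool a weekly incidence rate from a study table.

    The CSV must have columns ``label, events, n, followup_weeks``; the
    cumulative risk of each study is ``events / n`` and pooling weights are
    the study sizes.
    """
    table = pd.read_csv(path)
    required = {"label", "events", "n", "followup_weeks"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"study table is missing columns: {sorted(missing)}")
    studies = [
        StudyRisk(
            cumulative_risk=row.events / row.n,
            followup_weeks=row.followup_weeks,
            n_patients=int(row.n),
        )
        for row in table.itertuples()
    ]
    return pooled_incidence_rate(studies)


def relative_risk(counts: TwoByTwoCounts, level: float = 0.95) -> RREstimate:
    """Relative risk with a Katz log-normal confidence interval.

    The point estimate is the ratio of group risks; the interval
    exponentiates ``log RR ± z * SE`` with
    ``SE = sqrt(1/a - 1/n1 + 1/b - 1/n2)``.
    """
    a, n1 = counts.events_exposed, counts.n_exposed
    b, n2 = counts.events_reference, counts.n_reference
    if b == 0:
        raise UndefinedEstimateError(
            "relative risk is undefined with zero events in the reference group"
        )
    point = (a / n1) / (b / n2)
    if a == 0:
        # Point estimate collapses to zero; no log-scale interval exists.
        return RREstimate(0.0, 0.0, math.inf, level=level, reliable=False)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    z = stats.norm.ppf(0.5 + level / 2)
    return RREstimate(
        point,
        point * math.exp(-z * se),
        point * math.exp(z * se),
        level=level,
    )


def weekly_probability(ir_weekly: float, rr: float = 1.0) -> float:
    """Per-cycle transition probability from a weekly rate and a relative risk.

    The relative risk acts on the rate (hazard) scale:
    ``p = 1 - exp(-IR * RR)``.
    """
    if ir_weekly < 0:
        raise InvalidInputError(f"ir_weekly must be non-negative, got {ir_weekly}")
    if rr <= 0:
        raise InvalidInputError(f"rr must be positive, got {rr}")
    return -math.expm1(-ir_weekly * rr)


# ---------------------------------------------------------------------------
# Distribution back-calculation (for the probabilistic sensitivity analysis)
# ---------------------------------------------------------------------------

def sd_from_interval(low: float, high: float, level: float = 0.95) -> float:
    """Standard deviation implied by a normal confidence interval."""
    if low > high:
        raise InvalidInputError(f"interval bounds out of order: ({low}, {high})")
    if not 0.0 < level < 1.0:
        raise InvalidInputError(f"level must lie in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2)
    return (high - low) / (2 * z)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta shape parameters for a given mean and sd."""
    if not 0.0 < mean < 1.0:
        raise InvalidInputError(f"mean must lie in (0, 1), got {mean}")
    if sd < 0:
        raise InvalidInputError(f"sd must be non-negative, got {sd}")
    var = sd * sd
    if var >= mean * (1 - mean):
        raise InvalidVarianceError(
            f"sd^2 = {var:.6g} is infeasible for a Beta with mean {mean}"
        )
    factor = mean * (1 - mean) / var - 1
    return mean * factor, (1 - mean) * factor


def lognormal_from_ci(
    point: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching a ratio estimate and its CI."""
    if point <= 0 or ci_low <= 0 or ci_high <= 0:
        raise InvalidInputError("ratio estimates must be positive")
    if ci_low > ci_high:
        raise InvalidInputError("interval bounds out of order")
    z = stats.norm.ppf(0.5 + level / 2)
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
    return math.log(point), sigma


def binomial_ci(events: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion."""
    if n <= 0 or not 0 <= events <= n:
        raise InvalidInputError(f"invalid binomial counts {events}/{n}")
    alpha = 1 - level
    low = 0.0 if events == 0 else stats.beta.ppf(alpha / 2, events, n - events + 1)
    high = 1.0 if events == n else stats.beta.ppf(1 - alpha / 2, events + 1, n - events)
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def calibrate_resolution(
    points: Iterable[PrevalencePoint], horizon_weeks: int = 52
) -> ResolutionSchedule:
    """Weekly dysphagia-resolution probabilities fitted to prevalence anchors.

    Prevalence is interpolated linearly between the anchor points onto the
    weekly cycle grid (week ``w`` evaluated at day ``7w``; the final cycle
    absorbs the day-365 anchor so the terminal prevalence is hit exactly).
    A terminal anchor of zero prevalence at one year is appended when the
    input stops short of it, reflecting full resolution within a year.
    The per-week resolution probability is the conditional drop
    ``1 - prev(w)/prev(w-1)``.  Re-simulating the schedule without
    mortality reproduces the anchors exactly.
    """
    pts = sorted(points, key=lambda p: p.time_days)
    if not pts:
        raise InvalidInputError("calibration requires at least one prevalence point")
    if pts[0].time_days != 0 or pts[0].fraction_with_dysphagia != 1.0:
        raise InvalidInputError(
            "calibration must start from full prevalence at day 0"
        )
    fracs = [p.fraction_with_dysphagia for p in pts]
    if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
        raise CalibrationError("prevalence anchors must be non-increasing in time")
    if pts[-1].time_days < DAYS_PER_WEEK * horizon_weeks:
        pts.append(PrevalencePoint(YEAR_DAYS, 0.0))

    anchor_days = np.array([p.time_days for p in pts], dtype=float)
    anchor_prev = np.array([p.fraction_with_dysphagia for p in pts])
    grid_days = np.arange(horizon_weeks + 1, dtype=float) * DAYS_PER_WEEK
    # Terminal cycle stretches to the last anchor when it falls within a week
    # of the nominal grid end (day 365 vs 52 * 7 = 364).
    if 0 < anchor_days[-1] - grid_days[-1] < DAYS_PER_WEEK:
        grid_days[-1] = anchor_days[-1]
    prev = np.interp(grid_days, anchor_days, anchor_prev)

    probs = np.zeros(horizon_weeks)
    for w in range(1, horizon_weeks + 1):
        if prev[w - 1] <= 0.0:
            probs[w - 1] = 0.0
        else:
            probs[w - 1] = min(1.0, max(0.0, 1.0 - prev[w] / prev[w - 1]))
    return ResolutionSchedule(probs)


def mortality_schedule(
    p30: float, p90: float, p_rest: float, horizon_weeks: int = 52
) -> MortalitySchedule:
    """Piecewise-constant weekly death probabilities after stroke.

    ``p30`` applies during the first 30 days (weeks 1-4), ``p90`` through
    day 90 (weeks 5-13) and ``p_rest`` for the remainder of the horizon.
    """
    for name, p in (("p30", p30), ("p90", p90), ("p_rest", p_rest)):
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {p}")
    if horizon_weeks < 14:
        warnings.warn(
            f"horizon of {horizon_weeks} weeks truncates the mortality schedule",
            stacklevel=2,
        )
    probs = np.empty(horizon_weeks)
    probs[: min(4, horizon_weeks)] = p30
    if horizon_weeks > 4:
        probs[4: min(13, horizon_weeks)] = p90
    if horizon_weeks > 13:
        probs[13:] = p_rest
    return MortalitySchedule(probs)


def fit_log_survival(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Least-squares fit of cumulative mortality as ``a * ln(t) + b``.

    Returns ``(a, b, r_squared)``.  Used by the mortality scenario analysis
    to interpolate cumulative death risk between reported time points.
    """
    if len(points) < 2:
        raise InvalidInputError("log fit requires at least two points")
    t = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(t <= 0):
        raise InvalidInputError("time points must be positive")
    result = stats.linregress(np.log(t), y)
    return float(result.slope), float(result.intercept), float(result.rvalue ** 2)
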
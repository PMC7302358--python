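"""Weekly-cycle Markov cohort model of post-stroke dysphagia over one year.

States
------
The cohort moves between no-dysphagia, dysphagia-without-aspiration,
dysphagia-with-aspiration, a two-week aspiration-pneumonia tunnel (tagged
by the dysphagia state the patient came from and returns to), and death.
Death is absorbing; the pneumonia tunnel has forced duration: week 1 leads
only to week 2 or death, week 2 back to the originating dysphagia state or
death.

Mechanics
---------
Each cycle applies competing risks in the order death -> pneumonia onset ->
resolution/deterioration, with survivors split multiplicatively.  Pneumonia
onset converts the pooled weekly baseline incidence rate times a
state-specific relative risk to a probability on the hazard scale;
mortality inside the tunnel scales the weekly baseline hazard by the
pneumonia death relative risk.  Dysphagia resolution follows the
calibrated weekly schedule in both arms (the thickener is assumed not to
change dysphagia duration); deterioration moves non-aspirating patients to
the aspirating state (treatment failure).

The intervention cohort starts in dysphagia-without-aspiration (the
thickener removes fluid aspiration) and pays the weekly thickener cost for
every week spent with dysphagia; the comparator cohort starts in
dysphagia-with-aspiration.  A pneumonia episode is charged once on tunnel
entry; monitoring visits are charged to dysphagic occupants at the
scheduled weeks in both arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import FrozenSet

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .estimation import MortalitySchedule, ResolutionSchedule, weekly_probability
from .results import ARMS, COMPARATOR, INTERVENTION, ArmResult, CEComparison
from .static_model import WEEKS_PER_YEAR

__all__ = [
    "HealthState",
    "DynamicParams",
    "CohortTrace",
    "build_transition_row",
    "build_transition_matrix",
    "run_cohort",
    "accrue",
    "dynamic_cea",
]

DEFAULT_MONITORING_WEEKS = frozenset({1, 4, 12, 26, 39, 52})
#: Weekly thickener cost: 37.96 g/day * 7 days per 175 g tin at 77.05 PLN.
DEFAULT_NUTILIS_WEEKLY_COST = 37.96 * 7 / 175 * 77.05


class HealthState(IntEnum):
    NO_DYSPHAGIA = 0
    DYS_NO_ASP = 1
    DYS_ASP = 2
    AP1_FROM_NO_ASP = 3   # pneumonia week 1, entered from DYS_NO_ASP
    AP2_FROM_NO_ASP = 4
    AP1_FROM_ASP = 5      # pneumonia week 1, entered from DYS_ASP
    AP2_FROM_ASP = 6
    DEAD = 7


N_STATES = len(HealthState)

#: States in which the patient currently has dysphagia (tunnel weeks
#: included: a pneumonia episode does not cure the swallowing disorder).
DYSPHAGIA_STATES = (
    HealthState.DYS_NO_ASP,
    HealthState.DYS_ASP,
    HealthState.AP1_FROM_NO_ASP,
    HealthState.AP2_FROM_NO_ASP,
    HealthState.AP1_FROM_ASP,
    HealthState.AP2_FROM_ASP,
)

AP_ENTRY_STATES = (HealthState.AP1_FROM_NO_ASP, HealthState.AP1_FROM_ASP)


@dataclass(frozen=True)
class DynamicParams:
    """Complete parameter set for one Markov-model evaluation.

    Clinical defaults are the base case: pooled baseline pneumonia
    incidence 0.4036 %/week, relative risks 2.77 (dysphagia without
    aspiration), 8.27 (with aspiration) and 2.99 (death during pneumonia),
    deterioration 0.11 %/week.  ``resolution`` and ``mortality`` are the
    calibrated weekly schedules; ``u_no_dysphagia`` has no published base
    value and must be supplied (the shipped fixture carries a clearly
    flagged placeholder).
    """

    resolution: ResolutionSchedule
    mortality: MortalitySchedule
    u_no_dysphagia: float
    baseline_ap_ir_weekly: float = 0.004036
    rr_ap_no_asp: float = 2.77
    rr_ap_asp: float = 8.27
    rr_death_ap: float = 2.99
    deterioration_weekly: float = 0.0011
    u_dys_asp: float = 0.15
    u_dys_no_asp: float = 0.37
    du_ap: float = 0.13
    ap_tunnel_weeks: int = 2
    cost_ap_episode: float = 1924.0
    cost_monitoring_visit: float = 186.0
    monitoring_weeks: FrozenSet[int] = DEFAULT_MONITORING_WEEKS
    nutilis_weekly_cost: float = DEFAULT_NUTILIS_WEEKLY_COST
    horizon_weeks: int = 52
    monitoring_enabled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "monitoring_weeks",
                           frozenset(self.monitoring_weeks))
        for name in ("u_no_dysphagia", "u_dys_asp", "u_dys_no_asp",
                     "deterioration_weekly"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {value}")
        if self.du_ap < 0:
            raise InvalidInputError("du_ap must be non-negative")
        if self.baseline_ap_ir_weekly < 0:
            raise InvalidInputError("baseline_ap_ir_weekly must be non-negative")
        for name in ("rr_ap_no_asp", "rr_ap_asp", "rr_death_ap"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in ("cost_ap_episode", "cost_monitoring_visit",
                     "nutilis_weekly_cost"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.horizon_weeks < 0:
            raise InvalidInputError("horizon_weeks must be non-negative")
        if self.ap_tunnel_weeks != 2:
            raise InvalidInputError(
                "the pneumonia tunnel is structurally two weeks long"
            )
        bad_weeks = {w for w in self.monitoring_weeks
                     if not 1 <= w <= self.horizon_weeks}
        if bad_weeks:
            raise InvalidInputError(
                f"monitoring_weeks outside 1..{self.horizon_weeks}: "
                f"{sorted(bad_weeks)}"
            )
        for name, schedule in (("resolution", self.resolution),
                               ("mortality", self.mortality)):
            if schedule.horizon_weeks < self.horizon_weeks:
                raise InvalidInputError(
                    f"{name} schedule shorter than the {self.horizon_weeks}-week "
                    "horizon"
                )

    def state_utilities(self) -> np.ndarray:
        """Utility weight of each state; tunnel weeks carry the originating
        state's utility minus the pneumonia decrement."""
        u = np.zeros(N_STATES)
        u[HealthState.NO_DYSPHAGIA] = self.u_no_dysphagia
        u[HealthState.DYS_NO_ASP] = self.u_dys_no_asp
        u[HealthState.DYS_ASP] = self.u_dys_asp
        u[HealthState.AP1_FROM_NO_ASP] = self.u_dys_no_asp - self.du_ap
        u[HealthState.AP2_FROM_NO_ASP] = self.u_dys_no_asp - self.du_ap
        u[HealthState.AP1_FROM_ASP] = self.u_dys_asp - self.du_ap
        u[HealthState.AP2_FROM_ASP] = self.u_dys_asp - self.du_ap
        return u


@dataclass(frozen=True)
class CohortTrace:
    """Weekly state-occupancy fractions; row 0 is the starting cohort."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise InvalidInputError(
                f"occupancy must be (weeks+1, {N_STATES}), got {occ.shape}"
            )
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("occupancy rows must each sum to 1")
        if np.any((occ < -1e-12) | (occ > 1 + 1e-12)):
            raise InvalidInputError("occupancy fractions must lie in [0, 1]")

    @property
    def horizon_weeks(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, HealthState.DEAD]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (week, state, occupancy) view of the trace."""
        horizon = self.horizon_weeks
        return pd.DataFrame({
            "week": np.repeat(np.arange(horizon + 1), N_STATES),
            "state": [s.name for _ in range(horizon + 1) for s in HealthState],
            "occupancy": self.occupancy.ravel(),
        })


def _death_prob_in_ap(base_weekly: float, rr_death_ap: float) -> float:
    """Weekly baseline death hazard scaled by the pneumonia RR, capped at 1."""
    if base_weekly >= 1.0:
        return 1.0
    return min(1.0, -math.expm1(rr_death_ap * math.log1p(-base_weekly)))


def build_transition_row(
    state: HealthState, week: int, arm: str, params: DynamicParams
) -> np.ndarray:
    """One row of the transition matrix for the given cycle.

    ``week`` is 1-based.  Transitions are arm-independent (the arms differ
    in starting state and cost accrual); the argument is kept for interface
    symmetry and validated.
    """
    if arm not in ARMS:
        raise InvalidInputError(f"arm must be one of {ARMS}, got {arm!r}")
    if not 1 <= week <= params.horizon_weeks:
        raise InvalidInputError(
            f"week must lie in 1..{params.horizon_weeks}, got {week}"
        )
    m = params.mortality.weekly_death_prob[week - 1]
    r = params.resolution.weekly_resolution_prob[week - 1]
    d = params.deterioration_weekly
    row = np.zeros(N_STATES)

    if state == HealthState.DEAD:
        row[HealthState.DEAD] = 1.0
    elif state == HealthState.NO_DYSPHAGIA:
        row[HealthState.DEAD] = m
        row[HealthState.NO_DYSPHAGIA] = 1.0 - m
    elif state in (HealthState.DYS_NO_ASP, HealthState.DYS_ASP):
        rr = (params.rr_ap_no_asp if state == HealthState.DYS_NO_ASP
              else params.rr_ap_asp)
        p_ap = weekly_probability(params.baseline_ap_ir_weekly, rr)
        ap_target = (HealthState.AP1_FROM_NO_ASP
                     if state == HealthState.DYS_NO_ASP
                     else HealthState.AP1_FROM_ASP)
        survive = 1.0 - m
        row[HealthState.DEAD] = m
        row[ap_target] = survive * p_ap
        rest = survive * (1.0 - p_ap)
        row[HealthState.NO_DYSPHAGIA] = rest * r
        if state == HealthState.DYS_NO_ASP:
            row[HealthState.DYS_ASP] = rest * (1.0 - r) * d
            row[HealthState.DYS_NO_ASP] = rest * (1.0 - r) * (1.0 - d)
        else:
            row[HealthState.DYS_ASP] = rest * (1.0 - r)
    elif state in (HealthState.AP1_FROM_NO_ASP, HealthState.AP1_FROM_ASP):
        m_ap = _death_prob_in_ap(m, params.rr_death_ap)
        row[HealthState.DEAD] = m_ap
        target = (HealthState.AP2_FROM_NO_ASP
                  if state == HealthState.AP1_FROM_NO_ASP
                  else HealthState.AP2_FROM_ASP)
        row[target] = 1.0 - m_ap
    elif state in (HealthState.AP2_FROM_NO_ASP, HealthState.AP2_FROM_ASP):
        m_ap = _death_prob_in_ap(m, params.rr_death_ap)
        row[HealthState.DEAD] = m_ap
        origin = (HealthState.DYS_NO_ASP
                  if state == HealthState.AP2_FROM_NO_ASP
                  else HealthState.DYS_ASP)
        row[origin] = 1.0 - m_ap
    else:  # pragma: no cover - exhaustive over the enum
        raise InvalidInputError(f"unknown state {state!r}")
    return row


def build_transition_matrix(
    week: int, arm: str, params: DynamicParams
) -> np.ndarray:
    """Full row-stochastic transition matrix for one cycle."""
    return np.vstack(
        [build_transition_row(s, week, arm, params) for s in HealthState]
    )


def run_cohort(arm: str, params: DynamicParams) -> CohortTrace:
    """Propagate the cohort through ``horizon_weeks`` weekly cycles."""
    if arm not in ARMS:
        raise InvalidInputError(f"arm must be one of {ARMS}, got {arm!r}")
    start = (HealthState.DYS_NO_ASP if arm == INTERVENTION
             else HealthState.DYS_ASP)
    occupancy = np.zeros((params.horizon_weeks + 1, N_STATES))
    occupancy[0, start] = 1.0
    for week in range(1, params.horizon_weeks + 1):
        matrix = build_transition_matrix(week, arm, params)
        row_sums = matrix.sum(axis=1)
        assert np.allclose(row_sums, 1.0, atol=1e-9), (
            f"non-stochastic transition rows at week {week}: {row_sums}"
        )
        occupancy[week] = occupancy[week - 1] @ matrix
    return CohortTrace(occupancy)


def accrue(trace: CohortTrace, arm: str, params: DynamicParams) -> ArmResult:
    """Accumulate QALYs and costs over a cohort trace.

    Continuous quantities — utilities, the weekly thickener cost
    (intervention arm) and monitoring visits — accrue on start-of-cycle
    occupancy, so the week lived during cycle ``w`` is valued at the state
    the patient entered it in (no half-cycle correction).  The pneumonia
    episode cost is an event cost, charged on each entry into tunnel
    week 1.
    """
    if arm not in ARMS:
        raise InvalidInputError(f"arm must be one of {ARMS}, got {arm!r}")
    if trace.horizon_weeks != params.horizon_weeks:
        raise InvalidInputError(
            "trace horizon does not match the parameter horizon"
        )
    start_occ = trace.occupancy[:-1]  # cycle starts: weeks 0..horizon-1
    qaly = float((start_occ @ params.state_utilities()).sum()) / WEEKS_PER_YEAR

    dys_occ = start_occ[:, DYSPHAGIA_STATES].sum(axis=1)
    # Tunnel week 1 occupancy equals that week's new pneumonia entries
    # (the tunnel admits no stayers), so summing it counts episodes.
    ap_entries = float(trace.occupancy[1:, AP_ENTRY_STATES].sum())
    cost_ap = params.cost_ap_episode * ap_entries

    cost_dys = (params.nutilis_weekly_cost * float(dys_occ.sum())
                if arm == INTERVENTION else 0.0)

    cost_mon = 0.0
    if params.monitoring_enabled and params.monitoring_weeks:
        weeks = sorted(params.monitoring_weeks)
        cost_mon = params.cost_monitoring_visit * float(
            sum(dys_occ[w - 1] for w in weeks)
        )
    return ArmResult(
        arm=arm,
        qaly=qaly,
        cost_dysphagia_treatment=cost_dys,
        cost_ap_treatment=cost_ap,
        cost_monitoring=cost_mon,
    )


def dynamic_cea(params: DynamicParams) -> CEComparison:
    """Run both arms of the Markov model and compare them."""
    results = {}
    for arm in (INTERVENTION, COMPARATOR):
        trace = run_cohort(arm, params)
        results[arm] = accrue(trace, arm, params)
    return CEComparison(
        intervention=results[INTERVENTION],
        comparator=results[COMPARATOR],
    )
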
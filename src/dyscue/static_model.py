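"""Closed-form static cost-utility model with a fixed dysphagia duration.

The static model assumes every patient is dysphagic for a fixed course
(8 weeks in the base case) and may suffer at most one aspiration-pneumonia
episode within it.  Thickener treatment removes fluid aspiration, so the
intervention arm carries the no-aspiration utility and the lower pneumonia
risk observed in non-aspirators, plus the cost of the thickener course;
the comparator (routine clinical practice) carries the aspiration utility
and the aspirators' pneumonia risk at zero treatment cost.

Arm values:

    C_int  = C_thickener(course) + C_AP * p(AP | non-aspirators)
    Q_int  = U_no_asp * weeks/52 - dU_AP * ap_weeks/52 * p(AP | non-aspirators)
    C_comp = C_AP * p(AP | aspirators)
    Q_comp = U_asp * weeks/52 - dU_AP * ap_weeks/52 * p(AP | aspirators)

No discounting and no monitoring cost are applied over the 8-week horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError
from .results import ARMS, COMPARATOR, INTERVENTION, ArmResult, CEComparison

WEEKS_PER_YEAR = 52

__all__ = ["StaticParams", "nutilis_course_cost", "static_arm", "static_cea"]


@dataclass(frozen=True)
class StaticParams:
    """Complete parameter set for one static-model evaluation.

    Defaults are the base case: pneumonia risks from the observed 10/82
    (aspirators) and 1/57 (non-aspirators) cohorts, utilities 0.15/0.37
    with a 0.13 pneumonia decrement, a 1924 PLN pneumonia episode, and
    thickener dosed at 37.96 g/day from 175 g tins priced 77.05 PLN to
    the public payer.
    """

    dysphagia_weeks: int = 8
    ap_weeks: int = 2
    p_ap_aspirators: float = 10 / 82
    p_ap_non_aspirators: float = 1 / 57
    u_aspiration: float = 0.15
    u_no_aspiration: float = 0.37
    du_ap: float = 0.13
    cost_ap_episode: float = 1924.0
    nutilis_daily_g: float = 37.96
    tin_g: float = 175.0
    tin_price: float = 77.05

    def __post_init__(self) -> None:
        for name in ("p_ap_aspirators", "p_ap_non_aspirators",
                     "u_aspiration", "u_no_aspiration"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {value}")
        if self.du_ap < 0:
            raise InvalidInputError(f"du_ap must be non-negative, got {self.du_ap}")
        for name in ("cost_ap_episode", "nutilis_daily_g", "tin_g", "tin_price"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.dysphagia_weeks < 0 or self.ap_weeks < 0:
            raise InvalidInputError("durations must be non-negative")


def nutilis_course_cost(
    daily_g: float, days: float, tin_g: float, tin_price: float
) -> float:
    """Payer cost of a thickener course, allowing fractional tins.

    Consumption is pro-rated: ``daily_g * days / tin_g`` tins at the tin
    price, without rounding up to whole tins.
    """
    if min(daily_g, days, tin_price) < 0:
        raise InvalidInputError("consumption inputs must be non-negative")
    if tin_g <= 0:
        raise InvalidInputError(f"tin_g must be positive, got {tin_g}")
    return daily_g * days / tin_g * tin_price


def static_arm(params: StaticParams, arm: str) -> ArmResult:
    """Evaluate one arm of the static model."""
    if arm not in ARMS:
        raise InvalidInputError(f"arm must be one of {ARMS}, got {arm!r}")
    horizon_frac = params.dysphagia_weeks / WEEKS_PER_YEAR
    ap_frac = params.ap_weeks / WEEKS_PER_YEAR
    if arm == INTERVENTION:
        p_ap = params.p_ap_non_aspirators
        utility = params.u_no_aspiration
        treatment_cost = nutilis_course_cost(
            params.nutilis_daily_g,
            7 * params.dysphagia_weeks,
            params.tin_g,
            params.tin_price,
        )
    else:
        p_ap = params.p_ap_aspirators
        utility = params.u_aspiration
        treatment_cost = 0.0
    return ArmResult(
        arm=arm,
        qaly=utility * horizon_frac - params.du_ap * ap_frac * p_ap,
        cost_dysphagia_treatment=treatment_cost,
        cost_ap_treatment=params.cost_ap_episode * p_ap,
    )


def static_cea(params: StaticParams) -> CEComparison:
    """Both arms of the static model and their incremental comparison."""
    return CEComparison(
        intervention=static_arm(params, INTERVENTION),
        comparator=static_arm(params, COMPARATOR),
    )
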
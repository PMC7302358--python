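"""Result containers shared by the static and the Markov model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidInputError

INTERVENTION = "intervention"
COMPARATOR = "comparator"
ARMS = (INTERVENTION, COMPARATOR)


@dataclass(frozen=True)
class ArmResult:
    """Per-arm QALYs and costs with a component breakdown (PLN)."""

    arm: str
    qaly: float
    cost_dysphagia_treatment: float = 0.0
    cost_ap_treatment: float = 0.0
    cost_monitoring: float = 0.0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidInputError(f"arm must be one of {ARMS}, got {self.arm!r}")

    @property
    def cost_total(self) -> float:
        return (
            self.cost_dysphagia_treatment
            + self.cost_ap_treatment
            + self.cost_monitoring
        )


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of the intervention against routine practice.

    ``icur`` is the incremental cost-utility ratio (PLN per QALY); it is
    ``None`` when the QALY difference is zero or when one arm dominates
    (cheaper and more effective), in which case ``dominance`` is set.
    """

    intervention: ArmResult
    comparator: ArmResult
    delta_cost: float = field(init=False)
    delta_qaly: float = field(init=False)
    icur: Optional[float] = field(init=False)
    dominance: Optional[str] = field(init=False)

    def __post_init__(self) -> None:
        dc = self.intervention.cost_total - self.comparator.cost_total
        dq = self.intervention.qaly - self.comparator.qaly
        object.__setattr__(self, "delta_cost", dc)
        object.__setattr__(self, "delta_qaly", dq)
        if dq == 0.0:
            icur, dominance = None, "undefined"
        elif dc <= 0.0 and dq > 0.0:
            icur, dominance = None, "intervention_dominant"
        elif dc >= 0.0 and dq < 0.0:
            icur, dominance = None, "intervention_dominated"
        else:
            icur, dominance = dc / dq, None
        object.__setattr__(self, "icur", icur)
        object.__setattr__(self, "dominance", dominance)

    def net_monetary_benefit(self, threshold: float) -> float:
        """``threshold * dQALY - dCost`` at a willingness-to-pay threshold."""
        return threshold * self.delta_qaly - self.delta_cost
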
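"""Fixtures and simulators for fully self-contained testing.

``base_case_fixture`` returns the shipped base-case configuration: every
published main-text value plus explicitly flagged placeholders for the
two inputs that were only ever reported in supplementary material (the
dysphagia-prevalence anchors and the no-dysphagia utility).  The
simulators generate data with the statistical structure the estimation
stage assumes — binomial 2x2 outcome tables and prevalence trajectories
implied by a known weekly resolution schedule — so parameter-recovery and
calibration round-trips can be tested without any external data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InvalidInputError
from .estimation import (
    DAYS_PER_WEEK,
    PrevalencePoint,
    ResolutionSchedule,
    TwoByTwoCounts,
)
from .io import ModelConfig, load_config

__all__ = [
    "base_case_fixture",
    "write_fixture",
    "simulate_two_by_two",
    "simulate_prevalence",
]

_FIXTURE_NAME = "base_case.yaml"

SeedLike = Union[int, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def fixture_path() -> Path:
    """Location of the canonical base-case YAML shipped with the package."""
    return Path(resources.files("dyscue.data") / _FIXTURE_NAME)


def base_case_fixture() -> ModelConfig:
    """The complete base-case configuration.

    All main-text parameter values are present; the fields listed in
    ``config.assumed_fields`` (prevalence anchors, no-dysphagia utility)
    are reverse-engineered placeholders, not published values.
    """
    return load_config(fixture_path())


def write_fixture(path) -> Path:
    """Copy the canonical fixture YAML to ``path`` (for editing/inspection)."""
    target = Path(path)
    target.write_text(fixture_path().read_text())
    return target


def simulate_two_by_two(
    p_exposed: float,
    p_reference: float,
    n_exposed: int,
    n_reference: int,
    seed: SeedLike = None,
) -> TwoByTwoCounts:
    """Binomial 2x2 outcome table at the given group risks."""
    for name, p in (("p_exposed", p_exposed), ("p_reference", p_reference)):
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {p}")
    if n_exposed <= 0 or n_reference <= 0:
        raise InvalidInputError("group sizes must be positive")
    rng = _rng(seed)
    return TwoByTwoCounts(
        events_exposed=int(rng.binomial(n_exposed, p_exposed)),
        n_exposed=n_exposed,
        events_reference=int(rng.binomial(n_reference, p_reference)),
        n_reference=n_reference,
    )


def simulate_prevalence(
    schedule: ResolutionSchedule,
    anchor_days: Sequence[int],
    n_patients: Optional[int] = None,
    seed: SeedLike = None,
) -> list[PrevalencePoint]:
    """Dysphagia prevalence at given days under a weekly resolution schedule.

    Deterministic mode (``n_patients=None``) returns the exact fraction
    still dysphagic, linearly interpolated within weeks; stochastic mode
    draws binomial counts of size ``n_patients`` around those fractions.
    """
    prev = schedule.prevalence()
    horizon_days = schedule.horizon_weeks * DAYS_PER_WEEK
    week_days = np.arange(schedule.horizon_weeks + 1) * DAYS_PER_WEEK
    rng = _rng(seed) if n_patients is not None else None
    points = []
    for day in anchor_days:
        if day < 0 or day > horizon_days:
            raise InvalidInputError(
                f"anchor day {day} outside the {horizon_days}-day horizon"
            )
        fraction = float(np.interp(day, week_days, prev))
        if n_patients is not None:
            fraction = rng.binomial(n_patients, fraction) / n_patients
        points.append(PrevalencePoint(int(day), fraction))
    return points
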
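import numpy as np
import pytest

from dyscue import base_case_fixture
from dyscue.estimation import MortalitySchedule, ResolutionSchedule
from dyscue.markov import DynamicParams


@pytest.fixture(scope="session")
def base_config():
    return base_case_fixture()


@pytest.fixture
def zero_hazard_params():
    """Dynamic parameters with every hazard switched off (8-week horizon)."""
    return DynamicParams(
        resolution=ResolutionSchedule(np.zeros(8)),
        mortality=MortalitySchedule(np.zeros(8)),
        u_no_dysphagia=0.49,
        baseline_ap_ir_weekly=0.0,
        deterioration_weekly=0.0,
        monitoring_weeks=frozenset(),
        horizon_weeks=8,
    )


def make_dynamic_params(horizon=52, resolution=None, mortality=None, **kwargs):
    """DynamicParams with flat schedules unless overridden."""
    if resolution is None:
        resolution = ResolutionSchedule(np.zeros(horizon))
    elif np.isscalar(resolution):
        resolution = ResolutionSchedule(np.full(horizon, float(resolution)))
    if mortality is None:
        mortality = MortalitySchedule(np.zeros(horizon))
    elif np.isscalar(mortality):
        mortality = MortalitySchedule(np.full(horizon, float(mortality)))
    kwargs.setdefault("u_no_dysphagia", 0.49)
    kwargs.setdefault("monitoring_weeks", frozenset(
        w for w in (1, 4, 12, 26, 39, 52) if w <= horizon))
    return DynamicParams(
        resolution=resolution,
        mortality=mortality,
        horizon_weeks=horizon,
        **kwargs,
    )
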
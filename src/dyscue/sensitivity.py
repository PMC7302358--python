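"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis re-evaluates a model with each uncertain
parameter pushed to its lower and upper bound in turn (tornado rows);
scenario analysis applies multi-parameter overrides and switches; the
probabilistic analysis draws every uncertain parameter independently from
its assigned distribution each iteration and records the incremental cost
and QALY pair, from which cost-effectiveness acceptability curves are
computed as the fraction of draws with non-negative net monetary benefit
at each willingness-to-pay threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError
from .estimation import (
    beta_from_moments,
    binomial_ci,
    lognormal_from_ci,
    sd_from_interval,
)
from .io import ModelConfig, evaluate
from .results import CEComparison

__all__ = [
    "ParamRange",
    "TornadoRow",
    "PSASpec",
    "CEACCurve",
    "one_way_dsa",
    "scenario",
    "psa",
    "ceac",
]


# ---------------------------------------------------------------------------
# One-way deterministic analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    """Low/high bounds for one parameter, addressed by dotted path.

    ``source`` records where the bounds come from: a published confidence
    interval (``ci``), a stated range (``stated``), or an exact binomial
    interval derived from counts (``binomial_ci``).
    """

    path: str
    low: float
    high: float
    source: str = "stated"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise InvalidInputError(
                f"{self.path}: range bounds out of order ({self.low}, {self.high})"
            )

    @classmethod
    def from_counts(cls, path: str, events: int, n: int,
                    level: float = 0.95) -> "ParamRange":
        """Range from the exact (Clopper-Pearson) binomial interval."""
        low, high = binomial_ci(events, n, level)
        return cls(path, low, high, source="binomial_ci")


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    icur_at_low: float
    icur_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icur_at_high - self.icur_at_low)


def _icur_or_nan(comparison: CEComparison) -> float:
    return math.nan if comparison.icur is None else comparison.icur


def one_way_dsa(
    config: ModelConfig,
    ranges: Sequence[ParamRange],
    model: str = "static",
) -> list[TornadoRow]:
    """Tornado analysis: one row per range, sorted by descending span.

    Each row re-evaluates the model with exactly one parameter at its low
    and then its high bound, everything else at base.  Ties in span are
    broken by parameter name so the output is deterministic.
    """
    rows = []
    for prange in ranges:
        icur_low = _icur_or_nan(evaluate(
            config.with_overrides({prange.path: prange.low}), model))
        icur_high = _icur_or_nan(evaluate(
            config.with_overrides({prange.path: prange.high}), model))
        rows.append(TornadoRow(prange.path, icur_low, icur_high))
    return sorted(rows, key=lambda r: (-r.span, r.parameter))


def ranges_from_config(config: ModelConfig, model: str) -> list[ParamRange]:
    """Materialise the config's ``ranges`` block for one model."""
    out = []
    for entry in config.raw.get("ranges", []):
        path = entry["path"]
        if not path.startswith(model + "."):
            continue
        source = entry.get("source", "stated")
        if source == "binomial_ci":
            out.append(ParamRange.from_counts(
                path, int(entry["events"]), int(entry["n"]),
                float(entry.get("level", 0.95))))
        else:
            out.append(ParamRange(path, float(entry["low"]),
                                  float(entry["high"]), source=source))
    return out


def tornado_frame(rows: Iterable[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": r.parameter, "icur_at_low": r.icur_at_low,
          "icur_at_high": r.icur_at_high, "span": r.span} for r in rows]
    )


# ---------------------------------------------------------------------------
# Scenario (multi-way) analysis
# ---------------------------------------------------------------------------

_SCENARIO_SWITCHES = {"monitoring", "life_years_only", "model"}


def scenario(
    config: ModelConfig,
    overrides: Mapping[str, Any],
    model: str = "static",
) -> CEComparison:
    """Re-evaluate a model under a set of overrides and switches.

    ``overrides`` maps dotted parameter paths to replacement values; the
    special keys ``monitoring`` (bool, dynamic model) and
    ``life_years_only`` (bool: all living-state utilities set to 1 and
    the pneumonia decrement to 0, so effects count life-years) switch
    model behaviour rather than a single parameter.
    """
    plain = {}
    switches = {}
    for key, value in overrides.items():
        if key in _SCENARIO_SWITCHES:
            switches[key] = value
        elif "." in key:
            plain[key] = value
        else:
            raise ConfigError(f"scenario override {key!r}: unknown key")
    if switches.get("life_years_only"):
        if model == "static":
            plain.update({
                "static.u_aspiration": 1.0,
                "static.u_no_aspiration": 1.0,
                "static.du_ap": 0.0,
            })
        else:
            plain.update({
                "dynamic.u_no_dysphagia": 1.0,
                "dynamic.u_dys_asp": 1.0,
                "dynamic.u_dys_no_asp": 1.0,
                "dynamic.du_ap": 0.0,
            })
    if "monitoring" in switches:
        plain["dynamic.monitoring_enabled"] = bool(switches["monitoring"])
    return evaluate(config.with_overrides(plain), model)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASpec:
    """Distributional assumptions for the probabilistic analysis.

    ``distributions`` maps dotted parameter paths to distribution
    descriptors::

        {"dist": "beta", "mean": m, "sd": s}           # or "ci": [lo, hi]
        {"dist": "beta_counts", "events": x, "n": n}   # Beta(x, n - x)
        {"dist": "lognormal", "point": p, "ci": [lo, hi]}
        {"dist": "gamma", "mean": m, "sd": s}          # or "sd_frac": f
        {"dist": "fixed", "value": v}
    """

    distributions: Mapping[str, Mapping[str, Any]]
    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise InvalidInputError(
                f"n_iterations must be positive, got {self.n_iterations}"
            )

    @classmethod
    def from_config(cls, config: ModelConfig,
                    n_iterations: Optional[int] = None,
                    seed: Optional[int] = None) -> "PSASpec":
        block = config.raw.get("psa")
        if block is None:
            raise ConfigError("config has no 'psa' block")
        return cls(
            distributions=block.get("distributions", {}),
            n_iterations=int(n_iterations if n_iterations is not None
                             else block.get("n_iterations", 10_000)),
            seed=int(seed if seed is not None
                     else block.get("seed", config.seed)),
        )


def _draw(spec: Mapping[str, Any], n: int, rng: np.random.Generator,
          path: str) -> np.ndarray:
    kind = spec.get("dist")
    if kind == "fixed":
        return np.full(n, float(spec["value"]))
    if kind == "beta":
        mean = float(spec["mean"])
        sd = float(spec["sd"]) if "sd" in spec else sd_from_interval(
            *map(float, spec["ci"]), float(spec.get("level", 0.95)))
        if sd == 0.0:
            return np.full(n, mean)
        alpha, beta = beta_from_moments(mean, sd)
        return rng.beta(alpha, beta, size=n)
    if kind == "beta_counts":
        events, total = int(spec["events"]), int(spec["n"])
        if not 0 < events < total:
            raise InvalidInputError(
                f"{path}: beta_counts needs 0 < events < n, got {events}/{total}"
            )
        return rng.beta(events, total - events, size=n)
    if kind == "lognormal":
        lo, hi = map(float, spec["ci"])
        mu, sigma = lognormal_from_ci(float(spec["point"]), lo, hi,
                                      float(spec.get("level", 0.95)))
        return rng.lognormal(mu, sigma, size=n)
    if kind == "gamma":
        mean = float(spec["mean"])
        sd = float(spec["sd"]) if "sd" in spec else mean * float(spec["sd_frac"])
        if sd <= 0:
            return np.full(n, mean)
        shape = (mean / sd) ** 2
        return rng.gamma(shape, sd * sd / mean, size=n)
    raise ConfigError(f"{path}: unknown distribution {kind!r}")


def psa(
    config: ModelConfig,
    spec: PSASpec,
    model: str = "static",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Monte-Carlo parameter uncertainty analysis.

    Draws every parameter independently from its distribution each
    iteration, re-evaluates the model, and returns a frame with one row
    per draw: ``delta_cost``, ``delta_qaly`` and ``icur`` (NaN where the
    ratio is undefined or dominance applies).  Reproducible given
    ``spec.seed`` (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    draws = {path: _draw(dist, n, rng, path)
             for path, dist in spec.distributions.items()}
    records = np.empty((n, 2))
    for i in range(n):
        overrides = {path: float(values[i]) for path, values in draws.items()}
        comparison = evaluate(config.with_overrides(overrides), model)
        records[i] = (comparison.delta_cost, comparison.delta_qaly)
    frame = pd.DataFrame(records, columns=["delta_cost", "delta_qaly"])
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["icur"] = np.where(
            frame["delta_qaly"] != 0.0,
            frame["delta_cost"] / frame["delta_qaly"],
            np.nan,
        )
    return frame


@dataclass(frozen=True)
class CEACCurve:
    """Probability the intervention is cost-effective vs the threshold."""

    thresholds: np.ndarray
    prob_cost_effective: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        p = np.asarray(self.prob_cost_effective, dtype=float)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "prob_cost_effective", p)
        if t.shape != p.shape:
            raise InvalidInputError("thresholds and probabilities must align")
        if np.any((p < 0) | (p > 1)):
            raise InvalidInputError("probabilities must lie in [0, 1]")

    def at(self, threshold: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.prob_cost_effective[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "prob_cost_effective": self.prob_cost_effective,
        })


def ceac(samples: pd.DataFrame, thresholds: Sequence[float]) -> CEACCurve:
    """Acceptability curve from PSA draws.

    At each threshold the probability is the fraction of draws with
    non-negative net monetary benefit ``threshold * dQALY - dCost``.
    """
    if len(samples) == 0:
        raise InvalidInputError("ceac requires at least one PSA draw")
    thresholds = np.asarray(list(thresholds), dtype=float)
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    nmb = thresholds[:, None] * dq[None, :] - dc[None, :]
    return CEACCurve(thresholds, (nmb >= 0).mean(axis=1))


def probability_cost_effective(samples: pd.DataFrame, threshold: float) -> float:
    """Fraction of PSA draws cost-effective at a single threshold."""
    return ceac(samples, [threshold]).prob_cost_effective[0]
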
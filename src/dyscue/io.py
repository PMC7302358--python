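"""Configuration loading, validation and report serialization.

The whole analysis is driven by one YAML file with blocks ``meta``,
``static``, ``dynamic``, ``psa`` and ``ranges``.  :class:`ModelConfig`
wraps the validated raw mapping and builds the typed parameter objects on
demand, so sensitivity analyses can override any scalar through a dotted
path (``static.u_no_aspiration``) on a copied mapping and rebuild.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, is_dataclass, asdict
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidInputError
from .estimation import (
    PrevalencePoint,
    calibrate_resolution,
    fit_log_survival,
    mortality_schedule,
    MortalitySchedule,
    ResolutionSchedule,
)
from .markov import DynamicParams, dynamic_cea
from .results import CEComparison
from .static_model import StaticParams, static_cea

logger = logging.getLogger("dyscue")

__all__ = ["ModelConfig", "load_config", "write_report", "read_report", "evaluate"]

_STATIC_FIELDS = {
    "dysphagia_weeks", "ap_weeks", "p_ap_aspirators", "p_ap_non_aspirators",
    "u_aspiration", "u_no_aspiration", "du_ap", "cost_ap_episode",
    "nutilis_daily_g", "tin_g", "tin_price",
}

_DYNAMIC_SCALARS = {
    "baseline_ap_ir_weekly", "rr_ap_no_asp", "rr_ap_asp", "rr_death_ap",
    "deterioration_weekly", "u_no_dysphagia", "u_dys_asp", "u_dys_no_asp",
    "du_ap", "cost_ap_episode", "cost_monitoring_visit",
    "nutilis_weekly_cost", "horizon_weeks",
}

_BLOCK_FIELDS = {
    "static": _STATIC_FIELDS,
    "dynamic": _DYNAMIC_SCALARS | {
        "mortality", "resolution_anchors", "monitoring_weeks",
        "monitoring_enabled", "assumed",
    },
}


def _proportion(value: Any, field: str) -> float:
    """Accept a scalar probability or a ``{events, n}`` count pair."""
    if isinstance(value, Mapping):
        try:
            events, n = value["events"], value["n"]
        except KeyError as exc:
            raise ConfigError(
                f"{field}: count form requires 'events' and 'n'"
            ) from exc
        if n <= 0 or not 0 <= events <= n:
            raise ConfigError(f"{field}: invalid counts {events}/{n}")
        return events / n
    return float(value)


@dataclass(frozen=True)
class ModelConfig:
    """Validated analysis configuration.

    ``raw`` is the full mapping as loaded; ``assumed_fields`` lists the
    dynamic-block inputs that are placeholders rather than published
    values (they must be supplied or consciously accepted).
    """

    raw: dict

    # -- accessors -----------------------------------------------------

    @property
    def meta(self) -> dict:
        return self.raw.get("meta", {})

    @property
    def threshold(self) -> float:
        return float(self.meta.get("threshold", 147024.0))

    @property
    def seed(self) -> int:
        return int(self.meta.get("seed", 0))

    @property
    def assumed_fields(self) -> list[str]:
        return list(self.raw.get("dynamic", {}).get("assumed", []))

    def has_block(self, name: str) -> bool:
        return name in self.raw

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ModelConfig":
        """Copy of the config with dotted-path scalar overrides applied."""
        raw = copy.deepcopy(self.raw)
        for path, value in overrides.items():
            node = raw
            *parents, leaf = path.split(".")
            for key in parents:
                if not isinstance(node, dict) or key not in node:
                    raise ConfigError(f"override path {path!r}: no block {key!r}")
                node = node[key]
            if not isinstance(node, dict):
                raise ConfigError(f"override path {path!r} does not address a field")
            allowed = _BLOCK_FIELDS.get(parents[-1]) if parents else None
            if allowed is not None and leaf not in allowed:
                raise ConfigError(f"override path {path!r}: unknown field {leaf!r}")
            node[leaf] = value
        return ModelConfig(raw)

    # -- builders ------------------------------------------------------

    def static_params(self) -> StaticParams:
        block = self.raw.get("static")
        if block is None:
            raise ConfigError("config has no 'static' block")
        kwargs = {}
        for key, value in block.items():
            if key not in _STATIC_FIELDS:
                raise ConfigError(f"static.{key}: unknown parameter")
            if key.startswith("p_ap"):
                kwargs[key] = _proportion(value, f"static.{key}")
            else:
                kwargs[key] = value
        try:
            return StaticParams(**kwargs)
        except InvalidInputError as exc:
            raise ConfigError(f"static block invalid: {exc}") from exc

    def dynamic_params(self) -> DynamicParams:
        block = self.raw.get("dynamic")
        if block is None:
            raise ConfigError("config has no 'dynamic' block")
        block = dict(block)
        block.pop("assumed", None)
        horizon = int(block.get("horizon_weeks", 52))

        mort_raw = block.pop("mortality", None)
        if mort_raw is None:
            raise ConfigError("dynamic.mortality: missing block")
        mortality = _build_mortality(mort_raw, horizon)

        anchors_raw = block.pop("resolution_anchors", None)
        if anchors_raw is None:
            raise ConfigError(
                "dynamic.resolution_anchors: missing; supply the prevalence "
                "anchors or accept the shipped placeholder fixture"
            )
        try:
            anchors = [PrevalencePoint(int(d), float(f)) for d, f in anchors_raw]
            resolution = calibrate_resolution(anchors, horizon)
        except (InvalidInputError, ValueError, TypeError) as exc:
            raise ConfigError(f"dynamic.resolution_anchors invalid: {exc}") from exc

        monitoring = block.pop("monitoring_weeks", sorted(
            w for w in (1, 4, 12, 26, 39, 52) if w <= horizon))
        monitoring_enabled = bool(block.pop("monitoring_enabled", True))

        kwargs = {}
        for key, value in block.items():
            if key not in _DYNAMIC_SCALARS:
                raise ConfigError(f"dynamic.{key}: unknown parameter")
            kwargs[key] = value
        if "u_no_dysphagia" not in kwargs:
            raise ConfigError(
                "dynamic.u_no_dysphagia: required (no published base value; "
                "supply one or accept the flagged placeholder in the fixture)"
            )
        try:
            return DynamicParams(
                resolution=resolution,
                mortality=mortality,
                monitoring_weeks=frozenset(int(w) for w in monitoring),
                monitoring_enabled=monitoring_enabled,
                **kwargs,
            )
        except InvalidInputError as exc:
            raise ConfigError(f"dynamic block invalid: {exc}") from exc


def _build_mortality(mort_raw: Mapping[str, Any], horizon: int) -> MortalitySchedule:
    source = mort_raw.get("source", "piecewise")
    if source == "piecewise":
        try:
            return mortality_schedule(
                float(mort_raw["p30_weekly"]),
                float(mort_raw["p90_weekly"]),
                float(mort_raw["rest_weekly"]),
                horizon,
            )
        except KeyError as exc:
            raise ConfigError(f"dynamic.mortality: missing {exc}") from exc
        except InvalidInputError as exc:
            raise ConfigError(f"dynamic.mortality invalid: {exc}") from exc
    if source == "log_fit":
        points = mort_raw.get("log_fit_points")
        if not points:
            raise ConfigError(
                "dynamic.mortality.log_fit_points required for source=log_fit"
            )
        a, b, _ = fit_log_survival([(float(t), float(m)) for t, m in points])
        cum = np.zeros(horizon + 1)
        days = np.arange(1, horizon + 1) * 7.0
        cum[1:] = np.clip(a * np.log(days) + b, 0.0, 1.0)
        cum = np.maximum.accumulate(cum)
        weekly = np.zeros(horizon)
        alive = 1.0 - cum[:-1]
        mask = alive > 0
        weekly[mask] = (cum[1:] - cum[:-1])[mask] / alive[mask]
        return MortalitySchedule(np.clip(weekly, 0.0, 1.0))
    raise ConfigError(f"dynamic.mortality.source: unknown source {source!r}")


def load_config(path) -> ModelConfig:
    """Load and validate a YAML analysis configuration."""
    path = Path(path)
    with path.open() as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    config = ModelConfig(raw)
    # Eager validation of whichever model blocks are present.
    if config.has_block("static"):
        config.static_params()
    if config.has_block("dynamic"):
        params = config.dynamic_params()
        if config.assumed_fields:
            logger.info(
                "dynamic block uses placeholder values for: %s",
                ", ".join(config.assumed_fields),
            )
        del params
    if not (config.has_block("static") or config.has_block("dynamic")):
        raise ConfigError(f"{path}: needs a 'static' or 'dynamic' block")
    return config


def evaluate(config: ModelConfig, model: str) -> CEComparison:
    """Run the chosen model ('static' or 'dynamic') at the config values."""
    if model == "static":
        return static_cea(config.static_params())
    if model == "dynamic":
        return dynamic_cea(config.dynamic_params())
    raise InvalidInputError(f"model must be 'static' or 'dynamic', got {model!r}")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _comparison_rows(comparison: CEComparison) -> list[dict[str, Any]]:
    rows = []

    def add(category: str, i: float, c: float) -> None:
        rows.append({
            "category": category,
            "intervention": i,
            "comparator": c,
            "incremental": i - c,
        })

    add("effects_qaly", comparison.intervention.qaly, comparison.comparator.qaly)
    add("cost_total", comparison.intervention.cost_total,
        comparison.comparator.cost_total)
    add("cost_dysphagia_treatment",
        comparison.intervention.cost_dysphagia_treatment,
        comparison.comparator.cost_dysphagia_treatment)
    add("cost_ap_treatment", comparison.intervention.cost_ap_treatment,
        comparison.comparator.cost_ap_treatment)
    add("cost_monitoring", comparison.intervention.cost_monitoring,
        comparison.comparator.cost_monitoring)
    return rows


def write_report(
    comparison: CEComparison,
    path,
    format: Optional[str] = None,
    seed: Optional[int] = None,
) -> None:
    """Serialize a comparison as a cost-utility report (CSV or JSON).

    The rows mirror the published results table: per-arm effects, total
    costs with component breakdown, and the ICUR, at full precision with a
    rounded display value alongside.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise InvalidInputError(f"report format must be csv or json, got {fmt!r}")
    rows = _comparison_rows(comparison)
    if fmt == "csv":
        frame = pd.DataFrame(rows)
        icur_row = {
            "category": "icur_pln_per_qaly",
            "intervention": np.nan,
            "comparator": np.nan,
            "incremental": np.nan if comparison.icur is None else comparison.icur,
        }
        frame = pd.concat([frame, pd.DataFrame([icur_row])], ignore_index=True)
        frame["incremental_display"] = frame["incremental"].round(3)
        frame.to_csv(path, index=False)
        return
    payload = {
        "rows": rows,
        "delta_cost": comparison.delta_cost,
        "delta_qaly": comparison.delta_qaly,
        "icur": comparison.icur,
        "icur_display": (None if comparison.icur is None
                         else round(comparison.icur)),
        "dominance": comparison.dominance,
    }
    if seed is not None:
        payload["seed"] = seed
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
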
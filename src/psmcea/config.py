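"""Model configuration: YAML round-tripping and dotted parameter paths.

A :class:`Config` bundles everything one model run needs: global settings,
two (or more) strategy cost/utility profiles, OS/PFS survival curves per
strategy, and the low/high ranges driving deterministic sensitivity
analysis.  Sensitivity machinery addresses individual inputs by dotted
paths such as ``strategies.gumarontinib.drug_cost_pfs_cycle`` or
``settings.discount_rate``; a single logical parameter (e.g. a utility used
in both arms) carries several paths that are moved together.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .km_reconstruct import DigitizedCurve
from .psm_engine import AdverseEvent, ModelSettings, StrategyConfig
from .survfit import (
    KMCurve,
    ParametricCurve,
    ParametricModel,
    SurvivalCurve,
    hybrid_curve,
)


@dataclass(frozen=True)
class ParamRange:
    """Low/high bounds for one logical parameter (possibly several paths)."""

    paths: tuple
    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.paths, str):
            object.__setattr__(self, "paths", (self.paths,))
        else:
            object.__setattr__(self, "paths", tuple(self.paths))
        if not self.low <= self.high:
            raise ValueError(f"{self.label or self.paths}: low must not exceed high")


@dataclass
class Config:
    settings: ModelSettings
    strategies: dict  # name -> StrategyConfig, insertion order = (intervention, comparator)
    curves: dict  # name -> {"os": SurvivalCurve, "pfs": SurvivalCurve}
    dsa_ranges: list = field(default_factory=list)

    @property
    def strategy_order(self) -> list:
        return list(self.strategies)

    def copy(self) -> "Config":
        return copy.deepcopy(self)


# --- dotted-path access ----------------------------------------------------


def _step(obj, token):
    if isinstance(obj, dict):
        return obj[token]
    if isinstance(obj, (list, tuple)):
        return obj[int(token)]
    return getattr(obj, token)


def get_param(config: Config, path: str):
    obj = config
    for token in path.split("."):
        obj = _step(obj, token)
    return obj


def set_param(config: Config, path: str, value) -> None:
    tokens = path.split(".")
    obj = config
    for token in tokens[:-1]:
        obj = _step(obj, token)
    last = tokens[-1]
    if isinstance(obj, dict):
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        setattr(obj, last, value)


# --- curve (de)serialisation ----------------------------------------------


def curve_from_spec(spec: dict) -> SurvivalCurve:
    """Build a survival curve from a config mapping.

    Supported forms::

        {family: ..., params: {...}}                      # pure parametric
        {km: {time: [...], survival: [...]}}              # KM step curve
        {km: ..., family: ..., params: ..., switch_time}  # hybrid
    """
    km = None
    if "km" in spec:
        km_obj = spec["km"]
        if isinstance(km_obj, str):
            km = DigitizedCurve.from_csv(km_obj)
        elif isinstance(km_obj, DigitizedCurve):
            km = km_obj
        else:
            km = DigitizedCurve(
                np.asarray(km_obj["time"], dtype=float),
                np.asarray(km_obj["survival"], dtype=float),
            )
    model = None
    if "family" in spec:
        model = ParametricModel(spec["family"], dict(spec["params"]))
    if km is not None and model is not None:
        switch = float(spec.get("switch_time", km.times[-1]))
        return hybrid_curve(km, model, switch)
    if km is not None:
        return KMCurve(km)
    if model is not None:
        return ParametricCurve(model)
    raise ValueError("curve spec needs 'family' and/or 'km'")


def curve_to_spec(curve: SurvivalCurve) -> dict:
    if isinstance(curve, ParametricCurve):
        return {"family": curve.model.family, "params": dict(curve.model.params)}
    if isinstance(curve, KMCurve):
        return {
            "km": {
                "time": curve.curve.times.tolist(),
                "survival": curve.curve.survival.tolist(),
            }
        }
    # hybrid
    return {
        "km": {
            "time": curve.km.times.tolist(),
            "survival": curve.km.survival.tolist(),
        },
        "family": curve.model.family,
        "params": dict(curve.model.params),
        "switch_time": curve.switch_time,
    }


# --- whole-config (de)serialisation ---------------------------------------


def config_to_dict(config: Config) -> dict:
    strategies = {}
    for name, s in config.strategies.items():
        strategies[name] = {
            "drug_cost_pfs_cycle": s.drug_cost_pfs_cycle,
            "drug_cost_pd_cycle": s.drug_cost_pd_cycle,
            "utility_pfs": s.utility_pfs,
            "utility_pd": s.utility_pd,
            "end_of_life_cost": s.end_of_life_cost,
            "initial_visit_cost": s.initial_visit_cost,
            "pfs_management_cycle": s.pfs_management_cycle,
            "pd_management_cycle": s.pd_management_cycle,
            "adverse_events": [
                {
                    "name": ae.name,
                    "incidence": ae.incidence,
                    "cost": ae.cost,
                    "disutility": ae.disutility,
                    "duration_years": ae.duration_years,
                }
                for ae in s.adverse_events
            ],
            "dose_mix": s.dose_mix,
        }
    return {
        "settings": {
            "cycle_length_months": config.settings.cycle_length_months,
            "discount_rate": config.settings.discount_rate,
            "survival_floor": config.settings.survival_floor,
            "max_cycles": config.settings.max_cycles,
            "wtp": config.settings.wtp,
            "occupancy": config.settings.occupancy,
        },
        "strategies": strategies,
        "curves": {
            name: {ep: curve_to_spec(c) for ep, c in eps.items()}
            for name, eps in config.curves.items()
        },
        "dsa_ranges": [
            {"paths": list(r.paths), "low": r.low, "high": r.high, "label": r.label}
            for r in config.dsa_ranges
        ],
    }


def config_from_dict(obj: dict) -> Config:
    settings = ModelSettings(**obj.get("settings", {}))
    strategies = {}
    for name, s in obj["strategies"].items():
        s = dict(s)
        aes = [AdverseEvent(**ae) for ae in s.pop("adverse_events", [])]
        strategies[name] = StrategyConfig(name=name, adverse_events=aes, **s)
    curves = {
        name: {ep: curve_from_spec(spec) for ep, spec in eps.items()}
        for name, eps in obj.get("curves", {}).items()
    }
    ranges = [
        ParamRange(
            paths=tuple(r["paths"]),
            low=float(r["low"]),
            high=float(r["high"]),
            label=r.get("label", ""),
        )
        for r in obj.get("dsa_ranges", [])
    ]
    return Config(settings=settings, strategies=strategies, curves=curves, dsa_ranges=ranges)


def load_config(path) -> Config:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
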
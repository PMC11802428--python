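"""Three-state partitioned survival model with cost/QALY accounting.

State occupancy is read directly off overlaid OS and PFS curves at each
monthly cycle: the progression-free share is S_PFS (capped at S_OS), the
progressed share is S_OS - S_PFS, and the dead share is 1 - S_OS.  Costs and
utilities accumulate per cycle with annual discounting applied at monthly
resolution, and two strategies are compared on incremental cost per QALY.

Occupancy is evaluated at cycle start by default (no half-cycle correction);
a mid-cycle convention is available behind a settings flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .survfit import SurvivalCurve


def discount_factor(t_months, annual_rate: float):
    """Discount factor (1 + r)^(-t/12) for time t in months."""
    t_arr = np.asarray(t_months, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = (1.0 + annual_rate) ** (-t_arr / 12.0)
    return float(out) if t_arr.ndim == 0 else out


@dataclass
class ModelSettings:
    """Global model settings.

    cycle_length_months : fixed monthly cycles (1/12 year exactly).
    discount_rate : annual rate applied to both costs and outcomes.
    survival_floor : the horizon runs until modelled OS falls to this level
        in every arm (lifetime horizon: "until 99% of patients died").
    max_cycles : hard cap on the horizon.
    wtp : willingness-to-pay threshold, $ per QALY.
    occupancy : "cycle_start" (default) or "mid_cycle".
    """

    cycle_length_months: float = 1.0
    discount_rate: float = 0.05
    survival_floor: float = 0.01
    max_cycles: int = 480
    wtp: float = 35007.0
    occupancy: str = "cycle_start"

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValueError("discount rate must be in [0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be at least 1")
        if self.occupancy not in ("cycle_start", "mid_cycle"):
            raise ValueError("occupancy must be 'cycle_start' or 'mid_cycle'")


@dataclass
class AdverseEvent:
    """One grade >=3 adverse event: management cost and disutility applied once.

    ``disutility`` is stored as a positive magnitude; ``duration_years`` is
    how long the utility decrement persists (default one model cycle).
    """

    name: str
    incidence: float
    cost: float
    disutility: float
    duration_years: float = 1.0 / 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"AE {self.name!r}: incidence must be in [0, 1]")
        if self.cost < 0:
            raise ValueError(f"AE {self.name!r}: cost must be non-negative")


@dataclass
class StrategyConfig:
    """One treatment arm's costs, utilities and adverse-event profile (2023 USD)."""

    name: str
    drug_cost_pfs_cycle: float
    drug_cost_pd_cycle: float
    utility_pfs: float
    utility_pd: float
    end_of_life_cost: float
    initial_visit_cost: float = 0.0
    pfs_management_cycle: float = 0.0
    pd_management_cycle: float = 0.0
    adverse_events: list = field(default_factory=list)
    dose_mix: Optional[dict] = None  # {"full_dose": mg, "counts": {mg: n, ...}}

    def __post_init__(self) -> None:
        for fieldname in (
            "drug_cost_pfs_cycle",
            "drug_cost_pd_cycle",
            "end_of_life_cost",
            "initial_visit_cost",
            "pfs_management_cycle",
            "pd_management_cycle",
        ):
            if getattr(self, fieldname) < 0:
                raise ValueError(f"{fieldname} must be non-negative")
        for u in (self.utility_pfs, self.utility_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must be in [0, 1]")

    @property
    def ae_cost_once(self) -> float:
        return sum(ae.incidence * ae.cost for ae in self.adverse_events)

    @property
    def ae_qaly_decrement(self) -> float:
        return sum(
            ae.incidence * abs(ae.disutility) * ae.duration_years
            for ae in self.adverse_events
        )


@dataclass(frozen=True)
class Trace:
    """Per-cycle state occupancy, incident deaths and discount factors."""

    t: np.ndarray  # cycle-start times, months
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    incident_deaths: np.ndarray
    discount: np.ndarray

    @property
    def n_cycles(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_months": self.t,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "incident_deaths": self.incident_deaths,
                "discount": self.discount,
            }
        )


def horizon_cycles(os_curves: Sequence[SurvivalCurve], settings: ModelSettings) -> int:
    """Number of monthly cycles until OS <= survival_floor in every arm."""
    cl = settings.cycle_length_months
    grid = np.arange(settings.max_cycles + 1) * cl
    T = 1
    for curve in os_curves:
        s = np.asarray(curve.survival(grid))
        below = s <= settings.survival_floor
        T_arm = int(np.argmax(below)) if below.any() else settings.max_cycles
        T = max(T, min(max(T_arm, 1), settings.max_cycles))
    return T


def build_trace(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    settings: ModelSettings,
    n_cycles: Optional[int] = None,
) -> Trace:
    """Partition OS/PFS curves into per-cycle state occupancy.

    At each cycle the progression-free share is ``min(S_PFS, S_OS)`` (crossing
    tails are capped with a warning), the progressed share is the difference
    between OS and PFS, and incident deaths are the per-cycle increments of
    the dead share.
    """
    T = n_cycles if n_cycles is not None else horizon_cycles([os_curve], settings)
    cl = settings.cycle_length_months
    t = np.arange(T) * cl
    t_eval = t + 0.5 * cl if settings.occupancy == "mid_cycle" else t
    s_os = np.asarray(os_curve.survival(t_eval), dtype=float)
    s_pfs = np.asarray(pfs_curve.survival(t_eval), dtype=float)
    if np.any(~np.isfinite(s_os)) or np.any(~np.isfinite(s_pfs)):
        raise ValueError("survival curves are undefined at required cycle times")
    if np.any(s_pfs > s_os + 1e-12):
        warnings.warn("PFS exceeds OS at some cycles; capping PFS at OS")
    pfs = np.minimum(s_pfs, s_os)
    pd_state = s_os - pfs
    dead = 1.0 - s_os
    incident = np.diff(dead, prepend=0.0)
    disc = discount_factor(t, settings.discount_rate)
    return Trace(t=t, pfs=pfs, pd=pd_state, dead=dead, incident_deaths=incident, discount=disc)


@dataclass(frozen=True)
class ArmResults:
    """Accumulated (discounted and undiscounted) outcomes for one arm."""

    strategy: str
    ly_undiscounted: float
    ly_discounted: float
    qaly_discounted: float
    qaly_pfs: float
    qaly_pd: float
    qaly_ae_decrement: float
    qaly_undiscounted: float
    costs: dict  # discounted, by category
    costs_undiscounted: dict

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    @property
    def total_cost_undiscounted(self) -> float:
        return float(sum(self.costs_undiscounted.values()))


def accumulate(trace: Trace, strat: StrategyConfig, settings: ModelSettings) -> ArmResults:
    """Accumulate life-years, QALYs and per-category costs over a trace.

    Per cycle, occupancy x cycle length x (utility, unit costs) x discount
    factor; drug cost accrues at the on-treatment price in PFS and the
    post-progression chemotherapy price in PD; end-of-life cost is applied
    once to incident deaths in the cycle of death; adverse-event management
    cost and QALY decrement are applied once at model entry.
    """
    months = settings.cycle_length_months
    years = months / 12.0
    disc = trace.discount
    ones = np.ones_like(disc)

    def person_months(occ, d):
        return float(np.sum(occ * d)) * months

    ly_u = (person_months(trace.pfs, ones) + person_months(trace.pd, ones)) / 12.0
    ly_d = (person_months(trace.pfs, disc) + person_months(trace.pd, disc)) / 12.0

    ae_dec = strat.ae_qaly_decrement
    qaly_pfs = person_months(trace.pfs, disc) / 12.0 * strat.utility_pfs
    qaly_pd = person_months(trace.pd, disc) / 12.0 * strat.utility_pd
    qaly = qaly_pfs + qaly_pd - ae_dec
    qaly_u = (
        person_months(trace.pfs, ones) / 12.0 * strat.utility_pfs
        + person_months(trace.pd, ones) / 12.0 * strat.utility_pd
        - ae_dec
    )
    if qaly < 0:
        warnings.warn("negative total QALYs; clamping at 0")
        qaly = 0.0
    _ = years

    def costs_with(d):
        return {
            "drug_pfs": strat.drug_cost_pfs_cycle * person_months(trace.pfs, d) / months,
            "drug_pd": strat.drug_cost_pd_cycle * person_months(trace.pd, d) / months,
            "management": (
                strat.initial_visit_cost
                + strat.pfs_management_cycle * person_months(trace.pfs, d) / months
                + strat.pd_management_cycle * person_months(trace.pd, d) / months
            ),
            "ae": strat.ae_cost_once,
            "end_of_life": strat.end_of_life_cost * float(np.sum(trace.incident_deaths * d)),
        }

    return ArmResults(
        strategy=strat.name,
        ly_undiscounted=ly_u,
        ly_discounted=ly_d,
        qaly_discounted=qaly,
        qaly_pfs=qaly_pfs,
        qaly_pd=qaly_pd,
        qaly_ae_decrement=ae_dec,
        qaly_undiscounted=qaly_u,
        costs=costs_with(disc),
        costs_undiscounted=costs_with(ones),
    )


@dataclass(frozen=True)
class IncrementalResults:
    """Incremental comparison of strategy a versus strategy b."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    nmb: float
    dominant: Optional[str]  # "a" if a dominates, "b" if b dominates, else None
    wtp: float


def compare(a: ArmResults, b: ArmResults, wtp: float) -> IncrementalResults:
    """Incremental cost, QALYs, ICER and net monetary benefit of a vs b."""
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.qaly_discounted - b.qaly_discounted
    icer = d_cost / d_qaly if abs(d_qaly) > 0 else None
    nmb = wtp * d_qaly - d_cost
    dominant = None
    if d_qaly > 0 and d_cost < 0:
        dominant = "a"
    elif d_qaly < 0 and d_cost > 0:
        dominant = "b"
    return IncrementalResults(
        delta_cost=d_cost, delta_qaly=d_qaly, icer=icer, nmb=nmb,
        dominant=dominant, wtp=wtp,
    )


def run_psm(
    curves: dict,
    strategies: Sequence[StrategyConfig],
    settings: ModelSettings,
    n_cycles: Optional[int] = None,
) -> dict:
    """Run the partitioned survival model for every strategy on a common horizon.

    ``curves`` maps strategy name -> {"os": SurvivalCurve, "pfs": SurvivalCurve}.
    Returns {"arms": {name: ArmResults}, "traces": {name: Trace},
    "incremental": IncrementalResults (first vs second strategy) or None}.
    """
    os_curves = [curves[s.name]["os"] for s in strategies]
    T = n_cycles if n_cycles is not None else horizon_cycles(os_curves, settings)
    arms, traces = {}, {}
    for strat in strategies:
        trace = build_trace(curves[strat.name]["os"], curves[strat.name]["pfs"], settings, n_cycles=T)
        traces[strat.name] = trace
        arms[strat.name] = accumulate(trace, strat, settings)
    inc = None
    if len(strategies) >= 2:
        inc = compare(arms[strategies[0].name], arms[strategies[1].name], settings.wtp)
    return {"arms": arms, "traces": traces, "incremental": inc, "n_cycles": T}
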
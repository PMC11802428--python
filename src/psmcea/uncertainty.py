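"""Deterministic, probabilistic and scenario uncertainty analysis.

* One-way DSA: each parameter is pushed to its low and high bound with all
  others at base, and the model re-run; rows are sorted by net-monetary-
  benefit swing for tornado plotting.
* PSA: cost parameters draw from gamma distributions and utility /
  adverse-event-incidence parameters from beta distributions, both moment-
  matched to (mean, sd); per-draw incremental costs and QALYs feed the
  cost-effectiveness acceptability curve CEAC(lambda) = P(NMB(lambda) > 0).
* Scenarios: trial dose-mix price adjustment, a restricted (within
  follow-up) time horizon, and an exhaustive sweep over all combinations of
  parametric families for the four extrapolated curves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Config, ParamRange, get_param, set_param
from .psm_engine import accumulate, build_trace, compare, horizon_cycles, run_psm
from .survfit import FAMILIES, ParametricCurve, ParametricModel


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------


def _run(config: Config, n_cycles: Optional[int] = None) -> dict:
    strategies = [config.strategies[n] for n in config.strategy_order]
    return run_psm(config.curves, strategies, config.settings, n_cycles=n_cycles)


def run_model(config: Config, n_cycles: Optional[int] = None) -> dict:
    """Run the partitioned survival model described by a Config."""
    return _run(config, n_cycles=n_cycles)


def run_dsa(config: Config, ranges: Optional[Sequence[ParamRange]] = None) -> pd.DataFrame:
    """One-way sensitivity analysis over low/high parameter ranges.

    Returns a tornado table with ICER and NMB at each extreme, sorted by
    descending |NMB_high - NMB_low|.  A model failure at an extreme flags the
    row rather than aborting the analysis.
    """
    ranges = list(ranges) if ranges is not None else list(config.dsa_ranges)
    base = _run(config)["incremental"]
    rows = []
    for rng_ in ranges:
        row = {
            "parameter": rng_.label or rng_.paths[0],
            "low": rng_.low,
            "high": rng_.high,
            "base_icer": base.icer,
        }
        ok = True
        for bound, value in (("low", rng_.low), ("high", rng_.high)):
            cfg = config.copy()
            try:
                for path in rng_.paths:
                    set_param(cfg, path, value)
                inc = _run(cfg)["incremental"]
                row[f"icer_{bound}"] = inc.icer
                row[f"nmb_{bound}"] = inc.nmb
            except Exception as err:  # pragma: no cover - defensive
                warnings.warn(f"DSA failure for {row['parameter']} at {bound}: {err}")
                row[f"icer_{bound}"] = np.nan
                row[f"nmb_{bound}"] = np.nan
                ok = False
        row["failed"] = not ok
        if ok:
            row["nmb_swing"] = abs(row["nmb_high"] - row["nmb_low"])
            icers = [x for x in (row["icer_low"], row["icer_high"]) if x is not None]
            row["icer_range"] = max(icers) - min(icers) if icers else np.nan
        else:
            row["nmb_swing"] = np.nan
            row["icer_range"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("nmb_swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def gamma_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moment matching needs positive mean and sd")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def beta_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean and standard deviation."""
    if not 0 < mean < 1:
        raise ValueError("beta moment matching needs mean in (0, 1)")
    v = sd**2
    if v >= mean * (1 - mean):
        raise ValueError(
            f"beta moment matching infeasible: variance {v:.3g} >= m(1-m)"
        )
    nu = mean * (1 - mean) / v - 1.0
    return mean * nu, (1 - mean) * nu


@dataclass(frozen=True)
class PSAParam:
    """One sampled parameter: distribution family, mean, sd and config paths."""

    paths: tuple
    dist: str  # "gamma" or "beta"
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.paths, str):
            object.__setattr__(self, "paths", (self.paths,))
        if self.dist not in ("gamma", "beta"):
            raise ValueError("dist must be 'gamma' or 'beta'")


def _is_beta_path(path: str) -> bool:
    return any(tok in path for tok in ("utility", "incidence", "disutility"))


def build_psa_spec(
    config: Config,
    sd_fraction: float = 0.10,
    include_ae_incidence: bool = True,
) -> list:
    """Derive a PSA specification from the config's DSA ranges.

    Cost-like parameters get gamma distributions and utility / incidence
    parameters get beta distributions; the sd comes from the 95% CI width
    (high - low)/3.92 when a range exists, otherwise ``sd_fraction`` of the
    mean.  The discount rate is varied in DSA only, never sampled.
    """
    spec = []
    for rng_ in config.dsa_ranges:
        if any("discount" in p for p in rng_.paths):
            continue
        mean = float(get_param(config, rng_.paths[0]))
        sd = (rng_.high - rng_.low) / 3.92
        if sd <= 0:
            sd = sd_fraction * mean
        dist = "beta" if _is_beta_path(rng_.paths[0]) else "gamma"
        spec.append(PSAParam(rng_.paths, dist, mean, sd, rng_.label))
    if include_ae_incidence:
        for sname in config.strategy_order:
            strat = config.strategies[sname]
            for i, ae in enumerate(strat.adverse_events):
                path = f"strategies.{sname}.adverse_events.{i}.incidence"
                spec.append(
                    PSAParam(
                        (path,), "beta", ae.incidence, sd_fraction * ae.incidence,
                        f"{sname}: {ae.name} incidence",
                    )
                )
    return spec


def draw_psa_params(
    spec: Sequence[PSAParam], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` parameter sets; columns are labelled by first path."""
    cols = {}
    for p in spec:
        if p.sd == 0:
            warnings.warn(f"{p.label or p.paths[0]}: sd = 0, degenerate draws")
            draws = np.full(n, p.mean)
        elif p.dist == "gamma":
            shape, scale = gamma_moment_params(p.mean, p.sd)
            draws = rng.gamma(shape, scale, size=n)
        else:
            try:
                a, b = beta_moment_params(p.mean, p.sd)
            except ValueError as err:
                raise ValueError(f"{p.label or p.paths[0]}: {err}") from err
            draws = rng.beta(a, b, size=n)
        cols[p.paths[0]] = draws
    return pd.DataFrame(cols)


@dataclass
class PSAResults:
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray
    n_failed: int

    @property
    def mean_delta_cost(self) -> float:
        return float(np.mean(self.delta_cost))

    @property
    def mean_delta_qaly(self) -> float:
        return float(np.mean(self.delta_qaly))

    @property
    def icer_of_means(self) -> float:
        """Ratio of mean increments."""
        return self.mean_delta_cost / self.mean_delta_qaly

    def mean_icer(self, min_dqaly: float = 1e-6) -> float:
        """Mean of per-draw ICERs, excluding near-zero QALY differences."""
        keep = np.abs(self.delta_qaly) > min_dqaly
        return float(np.mean(self.delta_cost[keep] / self.delta_qaly[keep]))

    def ceac_at(self, wtp: float) -> float:
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0))

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})


def run_psa(
    config: Config,
    spec: Optional[Sequence[PSAParam]] = None,
    n: int = 1000,
    seed: int = 0,
    wtp_grid: Optional[Sequence[float]] = None,
) -> PSAResults:
    """Monte-Carlo PSA: ``n`` model evaluations with sampled parameters.

    Survival curves are not sampled, so state occupancy is computed once and
    only the accumulation step is repeated per draw.  Draws for which the
    model fails are discarded and counted; more than 1% failures is an error.
    """
    spec = list(spec) if spec is not None else build_psa_spec(config)
    rng = np.random.default_rng(seed)
    draws = draw_psa_params(spec, n, rng)
    path_map = {p.paths[0]: p.paths for p in spec}

    strategies = [config.strategies[nm] for nm in config.strategy_order]
    T = horizon_cycles([config.curves[s.name]["os"] for s in strategies], config.settings)
    traces = {
        s.name: build_trace(
            config.curves[s.name]["os"], config.curves[s.name]["pfs"],
            config.settings, n_cycles=T,
        )
        for s in strategies
    }

    d_cost, d_qaly = [], []
    failed = 0
    for i in range(n):
        cfg = config.copy()
        try:
            for col, paths in path_map.items():
                for path in paths:
                    set_param(cfg, path, float(draws.iloc[i][col]))
            a = accumulate(traces[strategies[0].name],
                           cfg.strategies[strategies[0].name], cfg.settings)
            b = accumulate(traces[strategies[1].name],
                           cfg.strategies[strategies[1].name], cfg.settings)
            inc = compare(a, b, cfg.settings.wtp)
        except Exception:  # pragma: no cover - defensive
            failed += 1
            continue
        d_cost.append(inc.delta_cost)
        d_qaly.append(inc.delta_qaly)
    if failed > 0.01 * n:
        raise RuntimeError(f"{failed} of {n} PSA draws failed")

    d_cost = np.asarray(d_cost)
    d_qaly = np.asarray(d_qaly)
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100001.0, 2500.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    nmb = wtp_grid[:, None] * d_qaly[None, :] - d_cost[None, :]
    ceac = (nmb > 0).mean(axis=1)
    return PSAResults(d_cost, d_qaly, wtp_grid, ceac, failed)


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------


def dose_mix_factor(counts: Mapping[float, int], full_dose: float) -> float:
    """Average delivered-dose fraction implied by a trial's dose mix.

    ``counts`` maps daily dose (mg) to the number of patients on it; the
    factor is the patient-weighted mean dose divided by the full dose, and
    scales the per-cycle drug acquisition cost.
    """
    total = sum(counts.values())
    if total <= 0 or full_dose <= 0:
        raise ValueError("dose mix requires positive counts and full dose")
    return float(sum(d * c for d, c in counts.items()) / (total * full_dose))


def run_dosage_scenario(config: Config) -> dict:
    """Re-run the model with each drug's cycle cost scaled by its dose mix."""
    cfg = config.copy()
    factors = {}
    for name in cfg.strategy_order:
        strat = cfg.strategies[name]
        if not strat.dose_mix:
            raise ValueError(f"strategy {name!r} has no dose_mix configured")
        f = dose_mix_factor(
            {float(k): v for k, v in strat.dose_mix["counts"].items()},
            float(strat.dose_mix["full_dose"]),
        )
        factors[name] = f
        strat.drug_cost_pfs_cycle *= f
    out = _run(cfg)
    out["dose_factors"] = factors
    return out


def run_horizon_scenario(config: Config, horizon_months: float = 30.0) -> dict:
    """Restricted-horizon run (e.g. trial follow-up only, no extrapolation).

    With KM curves supplied this is a within-follow-up analysis; with purely
    parametric curves the same truncation is applied to those and the output
    is labelled accordingly.
    """
    n_cycles = int(np.floor(horizon_months / config.settings.cycle_length_months))
    out = _run(config, n_cycles=n_cycles)
    kinds = {
        f"{name}.{ep}": curve.kind
        for name, eps in config.curves.items()
        for ep, curve in eps.items()
    }
    out["horizon_months"] = horizon_months
    out["truncated_curve_kinds"] = kinds
    out["note"] = (
        "restricted horizon applied to KM curves"
        if all(k in ("km_step", "hybrid") for k in kinds.values())
        else "restricted horizon applied to parametric curves (no KM supplied)"
    )
    return out


def run_distribution_sweep(
    config: Config,
    fitted: Mapping[str, Mapping[str, Mapping[str, ParametricModel]]],
    thresholds: Sequence[float] = (35007.0, 50000.0),
    families: Sequence[str] = FAMILIES,
) -> tuple[pd.DataFrame, dict]:
    """Exhaustive sweep over parametric families for the four curves.

    ``fitted`` maps strategy -> endpoint ("os"/"pfs") -> family ->
    ParametricModel; every combination of families across
    {strategy} x {endpoint} is run (len(families) ** 4 model evaluations)
    and the fraction of ICERs below each threshold reported.
    """
    names = list(config.strategy_order)
    slots = [(nm, ep) for nm in names for ep in ("os", "pfs")]
    for nm, ep in slots:
        missing = [f for f in families if f not in fitted.get(nm, {}).get(ep, {})]
        if missing:
            raise ValueError(
                f"sweep requested without fitted alternatives for {nm}/{ep}: {missing}"
            )
    rows = []
    for combo in itertools.product(families, repeat=len(slots)):
        cfg = config.copy()
        for (nm, ep), fam in zip(slots, combo):
            cfg.curves[nm][ep] = ParametricCurve(fitted[nm][ep][fam])
        inc = _run(cfg)["incremental"]
        row = {f"{nm}_{ep}": fam for (nm, ep), fam in zip(slots, combo)}
        row["icer"] = inc.icer if inc.icer is not None else np.nan
        row["delta_cost"] = inc.delta_cost
        row["delta_qaly"] = inc.delta_qaly
        rows.append(row)
    df = pd.DataFrame(rows)
    finite = df["icer"].notna() & (df["delta_qaly"] > 0)
    summary = {"n_runs": len(df)}
    for thr in thresholds:
        below = (df["icer"] < thr) & finite
        # dominant combinations (more QALYs, lower cost) also count as
        # cost-effective at any threshold
        dominant = (df["delta_qaly"] > 0) & (df["delta_cost"] < 0)
        summary[f"fraction_below_{int(thr)}"] = float((below | dominant).mean())
    return df, summary


def run_scenarios(
    config: Config,
    which: Sequence[str] = ("dosage", "horizon"),
    fitted=None,
    horizon_months: float = 30.0,
) -> dict:
    """Run the requested scenario analyses and return keyed results."""
    out = {}
    if "dosage" in which:
        out["dosage"] = run_dosage_scenario(config)
    if "horizon" in which:
        out["horizon"] = run_horizon_scenario(config, horizon_months)
    if "sweep" in which:
        if fitted is None:
            raise ValueError("distribution sweep requested without fitted alternatives")
        out["sweep"] = run_distribution_sweep(config, fitted)
    return out
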
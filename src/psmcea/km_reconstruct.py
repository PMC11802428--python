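"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published single-arm oncology trials rarely deposit patient-level data, but
they do print Kaplan-Meier survival curves and number-at-risk tables.  This
module reconstructs per-patient event and censoring times from those two
published artefacts and provides a weighted product-limit estimator so that
reconstructed (or reweighted) samples can be summarised the same way.

Conventions
-----------
* All times are months.
* A number-at-risk entry ``(t, n)`` is read as the count of patients still at
  risk immediately *after* time ``t``: events plotted exactly at a risk-table
  time are not included in that entry.  The companion
  :func:`psmcea.synthetic_data.digitize` uses the same convention, so
  round trips are exact at the tabulated times.
* When an event and a censoring coincide, the event is processed first
  (product-limit convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ReconstructionError(ValueError):
    """A digitized curve and risk table cannot be reconciled."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class DigitizedCurve:
    """An ordered set of (time, survival) coordinates read off a KM plot.

    The first point must be ``(0, 1)``; times strictly increase and survival
    is non-increasing within ``[0, 1]``.  Between coordinates the curve is
    treated as a right-continuous step function.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        s = np.atleast_1d(np.asarray(self.survival, dtype=float))
        if t.size == 0:
            raise ValueError("digitized curve is empty")
        if t.size != s.size:
            raise ValueError("times and survival must have equal length")
        if t[0] != 0.0 or s[0] != 1.0:
            raise ValueError("curve must start at (0, 1.0)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((s < -1e-12) | (s > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", np.clip(s, 0.0, 1.0))

    def survival_at(self, t):
        """Step-function survival at time(s) ``t`` (held beyond the last point)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        out = self.survival[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    @classmethod
    def from_csv(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["survival"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at tabulated times (first entry at time 0)."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        n = np.atleast_1d(np.asarray(self.n_at_risk, dtype=int))
        if t.size == 0 or t.size != n.size:
            raise ValueError("risk table times and counts must align and be non-empty")
        if t[0] != 0.0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("numbers at risk must be non-negative")
        if np.any(np.diff(n) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["n_at_risk"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "n_at_risk": self.n_at_risk}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed (or simulated) right-censored records.

    ``event`` is 1 for an observed event and 0 for censoring; ``weight``
    defaults to 1 per record and carries MAIC weights downstream.
    """

    time: np.ndarray
    event: np.ndarray
    weight: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.time, dtype=float))
        e = np.atleast_1d(np.asarray(self.event, dtype=int))
        if t.size == 0:
            raise ValueError("pseudo-IPD must contain at least one record")
        if t.size != e.size:
            raise ValueError("time and event must have equal length")
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("times must be positive and finite")
        if np.any((e != 0) & (e != 1)):
            raise ValueError("event indicators must be 0 or 1")
        w = self.weight
        if w is None:
            w = np.ones_like(t)
        else:
            w = np.atleast_1d(np.asarray(w, dtype=float))
            if w.size != t.size:
                raise ValueError("weights must align with records")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "weight", w)

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def with_weights(self, weights) -> "PseudoIPD":
        return PseudoIPD(self.time, self.event, np.asarray(weights, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event, "weight": self.weight}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PseudoIPD":
        w = df["weight"].to_numpy() if "weight" in df.columns else None
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), w)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------


def _simulate_interval(
    times, surv, point_idx, n_enter, km_enter, n_censor, lo_t, hi_t,
    fixed_d=None, placement="uniform",
):
    """Walk one risk-table interval with a trial censor count.

    Censoring times are spread uniformly over ``(lo_t, hi_t)``
    (``placement="uniform"``, drop-out censoring) or concentrated at the
    interval end (``placement="end"``, administrative censoring) and
    processed after the events of the digitized point they follow; censors
    beyond the remaining at-risk pool are dropped.  When ``fixed_d`` is
    given the event counts are taken as-is (replay mode) instead of being
    derived from the curve.  Returns the event count per point, the
    censoring times actually used, the number left at risk on exit and the
    product-limit value on exit.
    """
    if n_censor <= 0:
        cen_t = np.empty(0)
    elif placement == "end":
        cen_t = np.full(n_censor, hi_t)
    else:
        cen_t = lo_t + np.arange(1, n_censor + 1) * (hi_t - lo_t) / (n_censor + 1)

    d = np.zeros(len(point_idx), dtype=int)
    n = int(n_enter)
    km = float(km_enter)
    kept: list[float] = []

    first_t = times[point_idx[0]] if point_idx else np.inf
    pre = cen_t[cen_t < first_t]
    take = min(len(pre), n)
    kept.extend(pre[:take].tolist())
    n -= take

    for j, k in enumerate(point_idx):
        upper = times[point_idx[j + 1]] if j + 1 < len(point_idx) else np.inf
        if fixed_d is not None:
            dk = min(int(fixed_d[j]), n)
            if n > 0:
                km = km * (1.0 - dk / n)
        elif n > 0 and km > 0:
            dk = _round_half_up(n * (1.0 - surv[k] / km))
            dk = min(max(dk, 0), n)
            km = km * (1.0 - dk / n)
        else:
            dk = 0
        d[j] = dk
        n -= dk
        in_bin = cen_t[(cen_t >= times[k]) & (cen_t < upper)]
        take = min(len(in_bin), n)
        kept.extend(in_bin[:take].tolist())
        n -= take
    return d, np.asarray(kept), n, max(km, 0.0)


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: Optional[int] = None,
) -> PseudoIPD:
    """Reconstruct pseudo individual-patient data from a published KM curve.

    Within each pair of consecutive risk-table times the number of censored
    patients is estimated iteratively (censoring assumed uniform over the
    interval) so that the implied number at risk at the next tabulated time
    equals the published count exactly.  In the final, open-ended interval the
    censoring rate of the preceding follow-up is carried forward, and when
    ``total_events`` is supplied the final interval is re-balanced so the
    reconstructed event count honours it.

    Parameters
    ----------
    curve : digitized survival coordinates, starting at (0, 1).
    risk : published numbers at risk; the initial count sets the sample size.
    total_events : optional reported total number of events.

    Returns
    -------
    PseudoIPD with exactly ``risk.n_at_risk[0]`` records.
    """
    t = curve.times
    S = curve.survival
    rt = risk.times
    rn = risk.n_at_risk
    m = len(rt)

    if rn[0] < 2:
        raise ReconstructionError("initial number at risk must be at least 2")
    if rt[-1] > t[-1]:
        raise ReconstructionError(
            "risk table extends beyond the digitized curve (no common time range)"
        )

    # Partition digitized points (excluding the anchor at t=0) into risk
    # intervals (rt[i], rt[i+1]]; the last interval is open-ended.
    edges = np.append(rt, np.inf)
    point_sets = []
    for i in range(m):
        lo, hi = edges[i], edges[i + 1]
        point_sets.append([k for k in range(1, len(t)) if lo < t[k] <= hi])

    d_all = {}
    cen_times: list[float] = []
    n_cur = int(rn[0])
    km_cur = 1.0
    censored_so_far = 0
    last_interval_state = None  # (n_enter, km_enter, lo_t, hi_t)

    for i in range(m):
        pts = point_sets[i]
        lo_t = rt[i]
        hi_t = rt[i + 1] if i < m - 1 else t[-1]

        if i < m - 1:
            target = int(rn[i + 1])
            s_hi = float(curve.survival_at(rt[i + 1]))
            # Several censor counts can reproduce the published at-risk count;
            # among them, prefer the one whose reconstruction best matches the
            # digitized survival level at the interval boundary.
            exact_best = None
            near_best = None
            for placement in ("uniform", "end"):
                for nc_try in range(0, n_cur + 1):
                    sim = _simulate_interval(
                        t, S, pts, n_cur, km_cur, nc_try, lo_t, hi_t,
                        placement=placement,
                    )
                    d, cen_t, n_exit, km_exit = sim
                    if n_exit == target:
                        key = abs(km_exit - s_hi)
                        if exact_best is None or key < exact_best[0]:
                            exact_best = (key, sim, nc_try, placement)
                    else:
                        key = (abs(n_exit - target), abs(km_exit - s_hi))
                        if near_best is None or key < near_best[0]:
                            near_best = (key, sim, nc_try, placement)
            result = None
            if exact_best is not None:
                _, (d, cen_t, n_exit, km_exit), nc, _pl = exact_best
                result = (d, cen_t, n_exit, km_exit, nc)
            elif near_best is not None and near_best[0][0] <= 2 and pts:
                # integer rounding can make the exact count unreachable by
                # varying censors alone; absorb a +/-2 residual in the event
                # count at the interval's final digitized point
                _, (d, cen_t, n_exit, km_exit), nc, pl = near_best
                d = d.astype(int).copy()
                residual = n_exit - target
                if residual < 0 and d[-1] + residual < 0:
                    residual = -d[-1]  # cannot remove more events than exist
                d[-1] += residual
                d2, cen_t2, n_exit2, km_exit2 = _simulate_interval(
                    t, S, pts, n_cur, km_cur, nc, lo_t, hi_t, fixed_d=d, placement=pl
                )
                if n_exit2 == target:
                    result = (d2, cen_t2, n_exit2, km_exit2, nc)
            if result is None:
                raise ReconstructionError(
                    f"cannot match the number at risk {target} at t={rt[i + 1]:g} "
                    f"(interval {i}: the curve and risk table are inconsistent)"
                )
            d, cen_t, n_exit, km_exit, nc = result
        else:
            # Final interval: no closing at-risk count is published, so pick
            # the censor count whose reconstruction best reproduces the
            # digitized survival level at the end of follow-up (ties broken
            # towards the censoring rate carried forward from earlier
            # follow-up, the conventional assumption).
            span_prev = rt[-1] - rt[0]
            span_last = hi_t - lo_t
            if m > 1 and span_prev > 0 and span_last > 0:
                nc_carry = _round_half_up(censored_so_far * span_last / span_prev)
                nc_carry = min(max(nc_carry, 0), n_cur)
            else:
                nc_carry = 0
            last_interval_state = (n_cur, km_cur, lo_t, hi_t)
            s_final = S[-1]
            best = None
            for placement in ("uniform", "end"):
                for nc_try in range(0, n_cur + 1):
                    sim = _simulate_interval(
                        t, S, pts, n_cur, km_cur, nc_try, lo_t, hi_t,
                        placement=placement,
                    )
                    key = (abs(sim[3] - s_final), abs(nc_try - nc_carry))
                    if best is None or key < best[0]:
                        best = (key, sim, nc_try)
            (_, (d, cen_t, n_exit, km_exit), nc) = best

        for j, k in enumerate(pts):
            d_all[k] = d_all.get(k, 0) + int(d[j])
        cen_times.extend(cen_t.tolist())
        censored_so_far += nc
        n_cur, km_cur = n_exit, km_exit

    if total_events is not None:
        events_other = sum(
            d_all.get(k, 0) for i in range(m - 1) for k in point_sets[i]
        )
        needed_last = int(total_events) - events_other
        n_enter, km_enter, lo_t, hi_t = last_interval_state
        pts = point_sets[m - 1]
        # remove the provisional last-interval pass
        for k in pts:
            d_all.pop(k, None)
        cen_times = cen_times[: len(cen_times) - len(cen_t)]
        best = None
        for nc_try in range(0, n_enter + 1):
            d, ct, n_exit, km_exit = _simulate_interval(
                t, S, pts, n_enter, km_enter, nc_try, lo_t, hi_t
            )
            gap = abs(int(d.sum()) - needed_last)
            if best is None or gap < best[0]:
                best = (gap, d, ct, n_exit, km_exit)
            if gap == 0:
                break
        gap, d, ct, n_exit, km_exit = best
        d = d.astype(int)
        if gap != 0 and len(pts) > 0:
            # final adjustment pass: absorb the residual at the last point
            residual = needed_last - int(d.sum())
            take = min(residual, n_exit) if residual > 0 else max(residual, -d[-1])
            d[-1] += take
            n_exit -= max(take, 0)
        for j, k in enumerate(pts):
            d_all[k] = int(d[j])
        cen_times.extend(ct.tolist())
        n_cur = n_exit

    rec_t: list[float] = []
    rec_e: list[int] = []
    for k in sorted(d_all):
        rec_t.extend([t[k]] * d_all[k])
        rec_e.extend([1] * d_all[k])
    rec_t.extend(cen_times)
    rec_e.extend([0] * len(cen_times))
    # survivors at the end of follow-up are administratively censored
    rec_t.extend([t[-1]] * n_cur)
    rec_e.extend([0] * n_cur)

    if len(rec_t) != rn[0]:
        raise ReconstructionError(
            f"reconstruction produced {len(rec_t)} records for {rn[0]} patients"
        )
    order = np.lexsort((-np.asarray(rec_e), np.asarray(rec_t)))
    rec_t = np.asarray(rec_t, dtype=float)[order]
    rec_e = np.asarray(rec_e, dtype=int)[order]
    # guard against zero times from curves that drop at t=0+
    rec_t = np.maximum(rec_t, np.finfo(float).tiny)
    return PseudoIPD(rec_t, rec_e)


# ---------------------------------------------------------------------------
# Product-limit estimation
# ---------------------------------------------------------------------------


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Weighted Kaplan-Meier estimate of the survival function.

    Computes ``prod(1 - d_i/n_i)`` over distinct event times, with weights
    accumulated in both the event mass ``d_i`` and the at-risk mass ``n_i``.
    Ties between events and censorings keep the censored records at risk at
    the tied time.
    """
    w = ipd.weight
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(ipd.time, kind="stable")
    times = ipd.time[order]
    events = ipd.event[order]
    weights = w[order]

    total_w = weights.sum()
    event_mask = events == 1
    event_times = np.unique(times[event_mask])

    surv = [1.0]
    out_times = [0.0]
    s = 1.0
    for tau in event_times:
        n_at_risk = weights[times >= tau].sum()
        d = weights[(times == tau) & event_mask].sum()
        if n_at_risk <= 0:
            break
        s *= 1.0 - d / n_at_risk
        out_times.append(float(tau))
        surv.append(max(s, 0.0))
    _ = total_w
    return DigitizedCurve(np.asarray(out_times), np.asarray(surv))


def median_survival(curve: DigitizedCurve) -> Optional[float]:
    """Smallest time at which survival is <= 0.5, or None if never reached."""
    below = curve.survival <= 0.5
    if not below.any():
        return None
    return float(curve.times[int(np.argmax(below))])
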
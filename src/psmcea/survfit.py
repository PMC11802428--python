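"""Weighted parametric survival fitting and extrapolation curves.

Fits right-censored survival data by maximum likelihood for the six
parametric families conventionally used when extrapolating trial survival
beyond follow-up in economic models: exponential, Weibull, Gompertz,
log-logistic, lognormal and generalized gamma.  Per-record weights (for
example MAIC propensity weights) enter the log-likelihood directly:

    l(theta) = sum_i w_i [ e_i log f(t_i) + (1 - e_i) log S(t_i) ]

Candidate families are ranked by AIC (BIC reported alongside, with the
effective sample size of the weights as ``n``), and fitted tails can be
grafted onto a trial Kaplan-Meier curve to form the hybrid curves a
partitioned survival model consumes.

Parameter conventions (time in months)
--------------------------------------
exponential        rate                    S(t) = exp(-rate * t)
weibull            shape, scale            S(t) = exp(-(t/scale)^shape)
gompertz           shape (real), rate      h(t) = rate * exp(shape * t)
loglogistic        shape, scale            S(t) = 1 / (1 + (t/scale)^shape)
lognormal          meanlog, sdlog          S(t) = 1 - Phi((log t - meanlog)/sdlog)
generalized_gamma  mu, sigma, Q            Prentice (log-location mu, log-scale
                                           sigma > 0, shape Q); Q = 0 is the
                                           lognormal, Q = 1 the Weibull and
                                           Q = sigma the gamma special case
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .km_reconstruct import DigitizedCurve, PseudoIPD

FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "generalized_gamma",
)


class FitError(RuntimeError):
    """Maximum-likelihood fitting failed to converge."""


# --- log survival / log density per family (natural parameters) -----------


def _log_sf(family: str, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return -p[0] * t
    if family == "weibull":
        return -((t / p[1]) ** p[0])
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return -b * t
        return -b * np.expm1(a * t) / a
    if family == "loglogistic":
        return -np.log1p((t / p[1]) ** p[0])
    if family == "lognormal":
        return stats.norm.logsf((np.log(t) - p[0]) / p[1])
    if family == "generalized_gamma":
        mu, sigma, q = p
        if abs(q) < 1e-6:
            return stats.norm.logsf((np.log(t) - mu) / sigma)
        a = q**-2
        u = a * np.exp(q * (np.log(t) - mu) / sigma)
        with np.errstate(divide="ignore"):
            if q > 0:
                return np.log(special.gammaincc(a, u))
            return np.log(special.gammainc(a, u))
    raise ValueError(f"unknown family {family!r}")


def _log_pdf(family: str, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.log(p[0]) - p[0] * t
    if family == "weibull":
        k, s = p
        z = t / s
        return np.log(k / s) + (k - 1.0) * np.log(z) - z**k
    if family == "gompertz":
        a, b = p
        # f = h * S with h(t) = b exp(a t)
        return np.log(b) + a * t + _log_sf("gompertz", t, p)
    if family == "loglogistic":
        k, s = p
        z = t / s
        return np.log(k / s) + (k - 1.0) * np.log(z) - 2.0 * np.log1p(z**k)
    if family == "lognormal":
        mu, sg = p
        z = (np.log(t) - mu) / sg
        return stats.norm.logpdf(z) - np.log(sg * t)
    if family == "generalized_gamma":
        mu, sigma, q = p
        if abs(q) < 1e-6:
            z = (np.log(t) - mu) / sigma
            return stats.norm.logpdf(z) - np.log(sigma * t)
        a = q**-2
        w = (np.log(t) - mu) / sigma
        return (
            np.log(abs(q))
            - np.log(sigma * t)
            + a * np.log(a)
            - special.gammaln(a)
            + a * (q * w - np.exp(q * w))
        )
    raise ValueError(f"unknown family {family!r}")


# shape parameters that must stay positive are optimized on the log scale;
# the Gompertz shape and lognormal meanlog are unconstrained
_TRANSFORMS = {
    "exponential": (("log",), ("rate",)),
    "weibull": (("log", "log"), ("shape", "scale")),
    "gompertz": (("id", "log"), ("shape", "rate")),
    "loglogistic": (("log", "log"), ("shape", "scale")),
    "lognormal": (("id", "log"), ("meanlog", "sdlog")),
    "generalized_gamma": (("id", "log", "id"), ("mu", "sigma", "Q")),
}


def _pack(family: str, p: np.ndarray) -> np.ndarray:
    kinds, _ = _TRANSFORMS[family]
    return np.array(
        [np.log(v) if k == "log" else v for k, v in zip(kinds, p)], dtype=float
    )


def _unpack(family: str, theta: np.ndarray) -> np.ndarray:
    kinds, _ = _TRANSFORMS[family]
    return np.array(
        [np.exp(v) if k == "log" else v for k, v in zip(kinds, theta)], dtype=float
    )


def param_names(family: str) -> Sequence[str]:
    return _TRANSFORMS[family][1]


def _init_params(family: str, t, e, w) -> np.ndarray:
    tw = np.average(t, weights=w)
    rate0 = max(np.sum(w * e) / np.sum(w * t), 1e-6)
    logt = np.log(t)
    mu0 = np.average(logt, weights=w)
    sd0 = np.sqrt(max(np.average((logt - mu0) ** 2, weights=w), 1e-4))
    if family == "exponential":
        return np.array([rate0])
    if family == "weibull":
        k0 = min(max(1.2826 / sd0, 0.2), 5.0)
        return np.array([k0, max(tw, 1e-3)])
    if family == "gompertz":
        return np.array([1e-3, rate0])
    if family == "loglogistic":
        k0 = min(max(1.8138 / sd0, 0.2), 5.0)
        return np.array([k0, np.exp(mu0)])
    if family == "lognormal":
        return np.array([mu0, sd0])
    if family == "generalized_gamma":
        return np.array([mu0, sd0, 0.5])
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class ParametricModel:
    """A fitted (or specified) parametric survival model, time in months."""

    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        names = param_names(self.family)
        if set(self.params) != set(names):
            raise ValueError(
                f"{self.family} expects parameters {names}, got {sorted(self.params)}"
            )
        kinds, _ = _TRANSFORMS[self.family]
        for kind, name in zip(kinds, names):
            if kind == "log" and not self.params[name] > 0:
                raise ValueError(f"{self.family} parameter {name} must be positive")

    @property
    def _p(self) -> np.ndarray:
        return np.array([self.params[n] for n in param_names(self.family)])

    def survival(self, t):
        """S(t) for scalar or array t >= 0 (months)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be non-negative")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp(_log_sf(self.family, np.maximum(t_arr, 1e-300), self._p))
        out = np.where(t_arr == 0.0, 1.0, out)
        return float(out) if t_arr.ndim == 0 else out

    def inverse_survival(self, p: float) -> float:
        """Time t with S(t) = p, for p in (0, 1)."""
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        fam, par = self.family, self._p
        if fam == "exponential":
            return -np.log(p) / par[0]
        if fam == "weibull":
            return par[1] * (-np.log(p)) ** (1.0 / par[0])
        if fam == "gompertz":
            a, b = par
            if abs(a) < 1e-12:
                return -np.log(p) / b
            arg = 1.0 - a * np.log(p) / b
            if arg <= 0:
                return np.inf  # improper survival (negative shape plateau)
            return np.log(arg) / a
        if fam == "loglogistic":
            return par[1] * (1.0 / p - 1.0) ** (1.0 / par[0])
        if fam == "lognormal":
            return float(np.exp(par[0] + par[1] * stats.norm.isf(p)))
        if fam == "generalized_gamma":
            mu, sigma, q = par
            if abs(q) < 1e-6:
                return float(np.exp(mu + sigma * stats.norm.isf(p)))
            a = q**-2
            u = special.gammainccinv(a, p) if q > 0 else special.gammaincinv(a, p)
            return float(np.exp(mu + sigma * np.log(u / a) / q))
        raise ValueError(fam)

    def median(self) -> float:
        return self.inverse_survival(0.5)

    def curve(self) -> "ParametricCurve":
        return ParametricCurve(self)

    def to_json(self) -> str:
        return json.dumps(
            {"family": self.family, "params": self.params, "time_unit": "months"}
        )

    @classmethod
    def from_json(cls, text: str) -> "ParametricModel":
        obj = json.loads(text)
        return cls(obj["family"], obj["params"])


@dataclass(frozen=True)
class FitDiagnostics:
    family: str
    loglik: float
    n_params: int
    n_eff: float
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_eff) - 2.0 * self.loglik


def _nll(theta, family, t, e, w):
    p = _unpack(family, theta)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll = w * (e * _log_pdf(family, t, p) + (1 - e) * _log_sf(family, t, p))
    total = np.sum(ll)
    if not np.isfinite(total):
        return 1e12
    return -total


def fit_parametric(
    ipd: PseudoIPD,
    family: str,
    weights: Optional[np.ndarray] = None,
) -> tuple[ParametricModel, FitDiagnostics]:
    """Weighted maximum-likelihood fit of one parametric family.

    ``weights`` overrides the weights stored on the IPD; the effective sample
    size of the weights is used as ``n`` in the BIC penalty.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t = ipd.time
    e = ipd.event.astype(float)
    w = np.asarray(weights, dtype=float) if weights is not None else ipd.weight
    if w.shape != t.shape:
        raise ValueError("weights must align with the records")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.sum(w * e) <= 0:
        raise FitError("no (weighted) events: cannot fit a survival model")

    n_eff = float(np.sum(w) ** 2 / np.sum(w**2))

    if family == "exponential":
        rate = float(np.sum(w * e) / np.sum(w * t))
        model = ParametricModel("exponential", {"rate": rate})
        ll = -_nll(_pack("exponential", np.array([rate])), family, t, e, w)
        return model, FitDiagnostics(family, float(ll), 1, n_eff, True)

    p0 = _init_params(family, t, e, w)
    theta0 = _pack(family, p0)
    best = None
    for method in ("L-BFGS-B", "Nelder-Mead"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _nll,
                theta0,
                args=(family, t, e, w),
                method=method,
                options={"maxiter": 2000},
            )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        if best is not None and best.success:
            # polish with the other method from the current optimum
            theta0 = best.x
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError(f"{family} fit did not converge")
    grad = optimize.approx_fprime(best.x, _nll, 1e-6, family, t, e, w)
    converged = bool(best.success or np.max(np.abs(grad)) < 1e-2 * max(1.0, abs(best.fun)))
    if not converged:
        raise FitError(
            f"{family} fit did not converge (gradient inf-norm {np.max(np.abs(grad)):.3g})"
        )
    p_hat = _unpack(family, best.x)
    model = ParametricModel(family, dict(zip(param_names(family), p_hat.tolist())))
    diag = FitDiagnostics(family, float(-best.fun), len(p_hat), n_eff, converged)
    return model, diag


def fit_all(
    ipd: PseudoIPD,
    families: Sequence[str] = FAMILIES,
    weights: Optional[np.ndarray] = None,
) -> dict:
    """Fit several families, skipping (with a warning) any that fail."""
    out = {}
    for fam in families:
        try:
            out[fam] = fit_parametric(ipd, fam, weights=weights)
        except FitError as err:  # pragma: no cover - depends on data
            warnings.warn(f"skipping {fam}: {err}")
    if not out:
        raise FitError("no family could be fitted")
    return out


def rank_models(fits: Sequence[FitDiagnostics]) -> list[FitDiagnostics]:
    """Rank fits by ascending AIC; ties broken by fewer parameters."""
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: (f.aic, f.n_params))


def survival_at(model: ParametricModel, t) -> float:
    """Closed-form survival probability of ``model`` at time ``t`` months."""
    return model.survival(t)


# ---------------------------------------------------------------------------
# Curves consumed by the economic model
# ---------------------------------------------------------------------------


class SurvivalCurve:
    """Evaluable survival function S(t) over t >= 0 months."""

    kind = "abstract"

    def survival(self, t):  # pragma: no cover - interface
        raise NotImplementedError


class ParametricCurve(SurvivalCurve):
    kind = "parametric"

    def __init__(self, model: ParametricModel):
        self.model = model

    def survival(self, t):
        return self.model.survival(t)


class KMCurve(SurvivalCurve):
    """Step-function curve from digitized coordinates (held beyond support)."""

    kind = "km_step"

    def __init__(self, curve: DigitizedCurve):
        self.curve = curve

    def survival(self, t):
        return self.curve.survival_at(t)


class HybridCurve(SurvivalCurve):
    """KM curve within follow-up, ratio-anchored parametric tail beyond.

    S(t) = KM(t) for t <= switch_time and
    S(t) = KM(switch) * S_par(t) / S_par(switch) for t > switch_time,
    which is continuous at the switch by construction.
    """

    kind = "hybrid"

    def __init__(self, km: DigitizedCurve, model: ParametricModel, switch_time: float):
        if switch_time < 0 or switch_time > km.times[-1]:
            raise ValueError("switch_time must lie within the KM support")
        self.km = km
        self.model = model
        self.switch_time = float(switch_time)
        self._anchor_km = km.survival_at(switch_time)
        self._anchor_par = model.survival(switch_time)
        if self._anchor_par <= 0:
            raise ValueError("parametric survival is zero at the switch time")

    def survival(self, t):
        t_arr = np.asarray(t, dtype=float)
        par = np.asarray(self.model.survival(t_arr))
        tail = self._anchor_km * par / self._anchor_par
        km = np.asarray(self.km.survival_at(t_arr))
        out = np.where(t_arr <= self.switch_time, km, np.minimum(tail, self._anchor_km))
        out = np.clip(out, 0.0, 1.0)
        return float(out) if t_arr.ndim == 0 else out


def hybrid_curve(
    km: DigitizedCurve, model: ParametricModel, switch_time: float
) -> SurvivalCurve:
    """Join a trial KM curve to a parametric tail at ``switch_time``.

    ``switch_time = 0`` returns the pure parametric curve.
    """
    if switch_time == 0:
        return ParametricCurve(model)
    return HybridCurve(km, model, switch_time)


def curve_median(curve: SurvivalCurve, upper: float = 1200.0) -> Optional[float]:
    """Smallest time with S(t) <= 0.5 on a monthly grid refined by bisection."""
    grid = np.arange(0.0, upper + 1.0)
    s = np.asarray(curve.survival(grid))
    below = s <= 0.5
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return 0.0
    lo, hi = grid[i - 1], grid[i]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if curve.survival(mid) <= 0.5:
            hi = mid
        else:
            lo = mid
    return float(hi)
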
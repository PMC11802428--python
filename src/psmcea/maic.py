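"""Unanchored matching-adjusted indirect comparison (MAIC).

When two single-arm trials must be compared, patient-level data from the
index trial can be reweighted so its baseline covariate means match the
aggregate baselines published for the comparator trial.  The weights are the
method-of-moments propensity weights of Signorovitch-style MAIC: with
covariates centred at the target values, x_tilde_i = x_i - x*, minimising

    Q(alpha) = sum_i exp(x_tilde_i' alpha)

(a convex function) yields w_i = exp(x_tilde_i' alpha_hat) whose weighted
covariate means equal the targets exactly at the optimum.  The effective
sample size (sum w)^2 / sum w^2 quantifies the information retained.

Covariate screening follows the practice of selecting matching variables by
Cox proportional-hazards regression on the index-trial outcome (univariate
screen, then multivariate confirmation), with the option to force clinically
mandated covariates into the matching set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .km_reconstruct import DigitizedCurve, PseudoIPD, km_estimate


class InfeasibleTargetError(ValueError):
    """The aggregate target lies outside the observed covariate support."""


class WeightConvergenceError(RuntimeError):
    """The weight optimisation did not reach the moment conditions."""


@dataclass(frozen=True)
class WeightSet:
    """Per-patient MAIC weights with the fitted coefficient vector."""

    weights: np.ndarray
    alpha: np.ndarray
    covariates: tuple
    ess: float

    @property
    def n(self) -> int:
        return int(self.weights.size)


def effective_sample_size(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("at least one weight must be positive")
    return float(sw**2 / np.sum(w**2))


def estimate_weights(
    covs: pd.DataFrame,
    target: Mapping[str, float],
    rescale: bool = True,
    gtol: float = 1e-10,
) -> WeightSet:
    """Method-of-moments MAIC weights matching aggregate baselines.

    Parameters
    ----------
    covs : per-patient covariate matrix (binary/categorical already encoded
        as indicator columns; no missing values).
    target : covariate name -> target mean/proportion from the comparator
        trial's baseline table.
    rescale : rescale weights to sum to n (conventional; scale-invariant
        downstream).

    Returns
    -------
    WeightSet whose weighted covariate means equal the targets to 1e-8.
    """
    names = list(target)
    missing = [c for c in names if c not in covs.columns]
    if missing:
        raise KeyError(f"covariates not present in the matrix: {missing}")
    if covs[names].isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    X = covs[names].to_numpy(dtype=float)
    xstar = np.array([float(target[c]) for c in names])

    for j, c in enumerate(names):
        lo, hi = X[:, j].min(), X[:, j].max()
        if not (lo < xstar[j] < hi):
            raise InfeasibleTargetError(
                f"target {xstar[j]:g} for {c!r} is outside the observed "
                f"range ({lo:g}, {hi:g}); matching is infeasible"
            )

    Xc = X - xstar

    def q(alpha):
        return float(np.sum(np.exp(Xc @ alpha)))

    def grad(alpha):
        return Xc.T @ np.exp(Xc @ alpha)

    res = optimize.minimize(
        q, np.zeros(len(names)), jac=grad, method="BFGS", options={"gtol": gtol / 10, "maxiter": 500}
    )
    alpha = res.x
    gnorm = np.max(np.abs(grad(alpha)))
    if gnorm > gtol * max(1.0, q(alpha)):
        res2 = optimize.minimize(
            q, alpha, jac=grad, method="Newton-CG",
            hess=lambda a: (Xc * np.exp(Xc @ a)[:, None]).T @ Xc,
            options={"xtol": 1e-14, "maxiter": 200},
        )
        if q(res2.x) <= q(alpha):
            alpha = res2.x
            gnorm = np.max(np.abs(grad(alpha)))

    w = np.exp(Xc @ alpha)
    wmean = (w @ X) / w.sum()
    err = np.max(np.abs(wmean - xstar))
    if err > 1e-8:
        raise WeightConvergenceError(
            f"weighted means deviate from targets by {err:.3g} "
            f"(gradient inf-norm {gnorm:.3g})"
        )
    if rescale:
        w = w * (len(w) / w.sum())
    return WeightSet(
        weights=w,
        alpha=alpha,
        covariates=tuple(names),
        ess=effective_sample_size(w),
    )


def screen_covariates(
    ipd: PseudoIPD,
    covs: pd.DataFrame,
    alpha_level: float = 0.05,
    force_include: Sequence[str] = (),
) -> list:
    """Select matching covariates by Cox proportional-hazards screening.

    Each covariate is first screened univariately (partial-likelihood Wald
    p < ``alpha_level``); survivors are confirmed in a joint multivariate fit
    whose p-values govern the final selection.  Covariates in
    ``force_include`` are always retained (e.g. variables mandated by expert
    opinion), regardless of their p-values.

    Fits use Efron tie handling via :class:`lifelines.CoxPHFitter`.
    Covariates with monotone likelihood (complete separation) are excluded
    with a warning; a constant covariate is a precondition error.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if ipd.n_events < 2:
        raise ValueError("need at least two events for Cox screening")
    if len(covs) != ipd.n:
        raise ValueError("covariate matrix must align with the IPD")
    for c in covs.columns:
        if covs[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")

    base = pd.DataFrame({"time": ipd.time, "event": ipd.event})

    def cox_pvalues(columns):
        df = pd.concat([base, covs[columns].reset_index(drop=True)], axis=1)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        return cph.summary["p"]

    usable = []
    uni_sig = []
    for c in covs.columns:
        try:
            p = cox_pvalues([c])[c]
        except (ConvergenceError, ValueError) as err:
            warnings.warn(f"excluding covariate {c!r}: {err}")
            continue
        usable.append(c)
        if p < alpha_level:
            uni_sig.append(c)

    candidates = list(dict.fromkeys(list(uni_sig) + [c for c in force_include if c in usable]))
    if not candidates:
        return []
    if len(candidates) == 1:
        return candidates
    try:
        p_multi = cox_pvalues(candidates)
    except (ConvergenceError, ValueError) as err:
        raise RuntimeError(f"multivariate Cox fit failed: {err}") from err
    selected = [
        c for c in candidates if c in force_include or p_multi[c] < alpha_level
    ]
    return selected


def weighted_outcomes(
    ipd: PseudoIPD,
    weights: WeightSet,
    responses: Optional[Mapping[str, np.ndarray]] = None,
) -> tuple[DigitizedCurve, dict]:
    """Reweighted Kaplan-Meier curve and weighted binary-outcome proportions."""
    w = weights.weights
    if w.size != ipd.n:
        raise ValueError("weights must align with the IPD")
    curve = km_estimate(ipd.with_weights(w))
    props = {}
    if responses:
        for name, y in responses.items():
            y = np.asarray(y, dtype=float)
            if y.size != ipd.n:
                raise ValueError(f"response {name!r} must align with the IPD")
            props[name] = float(np.sum(w * y) / np.sum(w))
    return curve, props
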
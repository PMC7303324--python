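"""Per-animal compartmental fitting under a multiplicative error model.

The study's software fitted each animal's plasma profile with a
proportional (multiplicative) residual error.  The reproducible
maximum-likelihood equivalent is least squares on the log scale:

    minimise  sum_i ( ln C_obs,i  -  ln C_pred,i(theta) )^2

Optimisation runs in log-parameter space (positivity for free) with
deterministic curve-stripping initial estimates: the terminal slope of
the last points gives (beta, B); for the two-compartment model the fast
phase is recovered by residual peeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .design import PlasmaProfile
from .errors import EmptyProfileError, FitError
from .models import (
    OneCompartmentParams,
    Params,
    TwoCompartmentParams,
    macro_from_micro,
    predict,
)

__all__ = ["CompartmentalFit", "SecondaryParams", "exclude_bloq",
           "fit_profile", "derive_secondary"]


@dataclass(frozen=True)
class CompartmentalFit:
    """Result of fitting one plasma profile."""

    model: str                  # "1cpt" | "2cpt"
    params: Params
    sigma: float                # residual SD on the log (proportional) scale
    converged: bool
    n_observations: int
    cost: float                 # 0.5 * sum of squared log residuals
    n_iterations: int


@dataclass(frozen=True)
class SecondaryParams:
    """Derived parameters: Ke (1/h), T1/2 (h), Vss (L/kg), AUC0-inf (mg*h/L).

    For the two-compartment model Ke is reported as the terminal rate beta
    and Vss as V1 + V2.
    """

    Ke: float
    T_half_el: float
    Vss: float
    AUC_0_inf: float


def exclude_bloq(profile: PlasmaProfile) -> tuple[PlasmaProfile, int]:
    """Drop censored (below-LLOQ, incl. pre-dose) records from a profile.

    Returns a new profile plus the number of removed records; the input is
    untouched.  Raises EmptyProfileError when nothing survives.
    """
    keep = ~profile.censored
    n_removed = int(profile.censored.sum())
    if not keep.any():
        raise EmptyProfileError(
            f"all {profile.times.size} records of {profile.animal_id}/"
            f"{profile.analyte} are below the LLOQ")
    filtered = PlasmaProfile(
        animal_id=profile.animal_id,
        analyte=profile.analyte,
        times=profile.times[keep].copy(),
        concs=profile.concs[keep].copy(),
        lloq=profile.lloq,
        censored=np.zeros(int(keep.sum()), dtype=bool),
        dose_per_kg=profile.dose_per_kg,
    )
    return filtered, n_removed


def _terminal_slope(t: np.ndarray, logc: np.ndarray, n_tail: int = 3):
    """Slope/intercept of ln C over the last n_tail points."""
    tt, ll = t[-n_tail:], logc[-n_tail:]
    slope, intercept = np.polyfit(tt, ll, 1)
    return slope, intercept


def _init_1cpt(t, c, dose) -> OneCompartmentParams:
    logc = np.log(c)
    # all points: a 1cpt profile is globally log-linear
    slope, intercept = np.polyfit(t, logc, 1)
    ke = max(-slope, 1e-6)
    c0 = np.exp(intercept)
    V = max(dose / c0, 1e-9)
    return OneCompartmentParams(V=V, CL=ke * V)


def _init_2cpt(t, c, dose) -> TwoCompartmentParams:
    logc = np.log(c)
    n_tail = max(3, t.size // 3)
    slope, intercept = _terminal_slope(t, logc, n_tail)
    beta = max(-slope, 1e-6)
    B = np.exp(intercept)
    # residual peel over the early points
    resid = c - B * np.exp(-beta * t)
    early = resid > 0
    early[t >= t[-n_tail]] = False
    if early.sum() >= 2:
        a_slope, a_int = np.polyfit(t[early], np.log(resid[early]), 1)
        alpha = max(-a_slope, beta * 5.0)
        A = np.exp(a_int)
    else:  # fall back to a generic fast phase
        alpha = beta * 10.0
        A = max(c[0] - B, 0.1 * B)
    # macro -> micro
    c0 = A + B
    k21 = (A * beta + B * alpha) / c0
    k10 = alpha * beta / k21
    k12 = max(alpha + beta - k10 - k21, 1e-8)
    V1 = max(dose / c0, 1e-9)
    return TwoCompartmentParams(V1=V1, CL=k10 * V1, Q=k12 * V1, V2=k12 * V1 / k21)


def _pack(params: Params) -> np.ndarray:
    if isinstance(params, OneCompartmentParams):
        return np.log([params.V, params.CL])
    return np.log([params.V1, params.CL, params.Q, params.V2])


def _unpack(x: np.ndarray, model: str) -> Params:
    v = np.exp(x)
    if model == "1cpt":
        return OneCompartmentParams(V=v[0], CL=v[1])
    return TwoCompartmentParams(V1=v[0], CL=v[1], Q=v[2], V2=v[3])


def fit_profile(profile: PlasmaProfile, model: str, dose_per_kg: Optional[float] = None,
                init: Optional[Params] = None) -> CompartmentalFit:
    """Fit a BLOQ-filtered plasma profile by log-scale least squares.

    model is "1cpt" or "2cpt"; dose defaults to the profile's own dose.
    Deterministic for fixed inputs.  Raises FitError (carrying the best
    parameters seen) on non-convergence, ValueError on unusable input.
    """
    if model not in ("1cpt", "2cpt"):
        raise ValueError(f"unknown model {model!r}")
    dose = profile.dose_per_kg if dose_per_kg is None else dose_per_kg
    mask = ~profile.censored
    t = profile.times[mask]
    c = profile.concs[mask]
    if np.any(t == 0):
        raise ValueError("pre-dose (t=0) samples must be excluded before fitting")
    if np.any(c <= 0):
        raise ValueError("nonpositive concentrations cannot be log-fitted")
    n_par = 2 if model == "1cpt" else 4
    if t.size < n_par + 1:
        raise EmptyProfileError(
            f"{t.size} quantified points are too few for a {model} fit")

    if init is None:
        init = _init_1cpt(t, c, dose) if model == "1cpt" else _init_2cpt(t, c, dose)
    logc = np.log(c)

    def residuals(x):
        pred = predict(_unpack(x, model), dose, t)
        return np.log(pred) - logc

    sol = least_squares(residuals, _pack(init), method="lm", xtol=1e-12,
                        ftol=1e-12, gtol=1e-12, max_nfev=2000)
    params = _unpack(sol.x, model)
    dof = max(t.size - n_par, 1)
    fit = CompartmentalFit(
        model=model, params=params,
        sigma=float(np.sqrt(2.0 * sol.cost / dof)),
        converged=bool(sol.success), n_observations=int(t.size),
        cost=float(sol.cost), n_iterations=int(sol.nfev),
    )
    if not sol.success:
        raise FitError(f"fit did not converge: {sol.message}", best_fit=fit)
    return fit


def derive_secondary(fit: CompartmentalFit, dose_per_kg: float) -> SecondaryParams:
    """Secondary parameters from a converged structural fit.

    1cpt: Ke = CL/V, Vss = V.  2cpt: Ke = terminal rate beta, Vss = V1+V2.
    T1/2 = ln 2 / Ke; AUC(0, inf) = dose / CL for either model.
    """
    p = fit.params
    if isinstance(p, OneCompartmentParams):
        ke = p.ke
        vss = p.V
    else:
        _, _, _, beta = macro_from_micro(p)
        ke = beta
        vss = p.Vss
    return SecondaryParams(
        Ke=float(ke),
        T_half_el=float(np.log(2.0) / ke),
        Vss=float(vss),
        AUC_0_inf=float(dose_per_kg / p.CL),
    )
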
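"""Closed-form one- and two-compartment IV-bolus disposition models.

Both models are linear with first-order elimination; the same code path
simulates concentration-time curves and serves as the prediction
function during fitting.  Parameters are stored in the clearance
parameterisation (volumes and clearances, all per kg of body weight)
because those are the quantities with physiological meaning; macro
constants (A, B, alpha, beta) are derived on demand and never stored.

Units follow :mod:`renalcocktail.units`: dose mg/kg, volume L/kg,
clearance L/h/kg, time h, concentration mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

__all__ = [
    "OneCompartmentParams",
    "TwoCompartmentParams",
    "predict_1cpt",
    "predict_2cpt",
    "macro_from_micro",
    "auc_analytic",
]


@dataclass(frozen=True)
class OneCompartmentParams:
    """Monoexponential disposition: volume V (L/kg), clearance CL (L/h/kg).

    The elimination rate constant is ``ke = CL / V`` (1/h).
    """

    V: float
    CL: float

    def __post_init__(self):
        if self.V <= 0 or self.CL <= 0:
            raise ValueError(f"V and CL must be positive, got V={self.V}, CL={self.CL}")

    @property
    def ke(self) -> float:
        return self.CL / self.V


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Biexponential disposition in the clearance parameterisation.

    V1, V2 : central and peripheral volumes (L/kg)
    CL     : total body clearance (L/h/kg), elimination from central
    Q      : intercompartmental clearance (L/h/kg)

    Micro rate constants: k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.
    Steady-state volume is taken as ``Vss = V1 + V2``.
    """

    V1: float
    CL: float
    Q: float
    V2: float

    def __post_init__(self):
        for name in ("V1", "CL", "Q", "V2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2

    @property
    def Vss(self) -> float:
        return self.V1 + self.V2


Params = Union[OneCompartmentParams, TwoCompartmentParams]


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def predict_1cpt(params: OneCompartmentParams, dose_per_kg: float, t):
    """Concentration (mg/L) of a one-compartment IV bolus at time(s) t (h).

    C(t) = (dose/V) * exp(-ke * t), strictly decreasing in t.
    """
    t = _check_times(t)
    return (dose_per_kg / params.V) * np.exp(-params.ke * t)


def macro_from_micro(params: TwoCompartmentParams) -> Tuple[float, float, float, float]:
    """Macro constants (A1, B1, alpha, beta) of the two-compartment bolus model.

    The dose-normalised curve is ``C(t)/dose = A1*exp(-alpha t) + B1*exp(-beta t)``
    with alpha > beta > 0 roots of ``s^2 - (k10+k12+k21) s + k10 k21 = 0``.
    A1 + B1 = 1/V1 so that C(0) = dose/V1.

    Raises ValueError on the degenerate alpha == beta case (measure-zero in
    the clearance parameterisation; no fallback is attempted).
    """
    k10, k12, k21 = params.k10, params.k12, params.k21
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    # disc = (k10+k12-k21)^2 + 4 k12 k21 > 0 for positive rates, but guard anyway
    if disc <= 0:
        raise ValueError("degenerate two-compartment model: alpha == beta")
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    if alpha == beta:
        raise ValueError("degenerate two-compartment model: alpha == beta")
    c0 = 1.0 / params.V1
    a1 = c0 * (alpha - k21) / (alpha - beta)
    b1 = c0 * (k21 - beta) / (alpha - beta)
    return a1, b1, alpha, beta


def predict_2cpt(params: TwoCompartmentParams, dose_per_kg: float, t):
    """Concentration (mg/L) of a two-compartment IV bolus at time(s) t (h)."""
    t = _check_times(t)
    a1, b1, alpha, beta = macro_from_micro(params)
    return dose_per_kg * (a1 * np.exp(-alpha * t) + b1 * np.exp(-beta * t))


def predict(params: Params, dose_per_kg: float, t):
    """Dispatch on parameter type."""
    if isinstance(params, OneCompartmentParams):
        return predict_1cpt(params, dose_per_kg, t)
    return predict_2cpt(params, dose_per_kg, t)


def auc_analytic(params: Params, dose_per_kg: float, t1: float, t2: float = np.inf) -> float:
    """Exact integral of the predicted curve over [t1, t2] (mg*h/L).

    For either model AUC(0, inf) = dose / CL.
    """
    if t1 < 0 or not t1 < t2:
        raise ValueError(f"need 0 <= t1 < t2, got ({t1}, {t2})")
    if isinstance(params, OneCompartmentParams):
        ke = params.ke
        c0 = dose_per_kg / params.V
        upper = 0.0 if np.isinf(t2) else np.exp(-ke * t2)
        return float(c0 / ke * (np.exp(-ke * t1) - upper))
    a1, b1, alpha, beta = macro_from_micro(params)
    terms = 0.0
    for coef, lam in ((a1, alpha), (b1, beta)):
        upper = 0.0 if np.isinf(t2) else np.exp(-lam * t2)
        terms += coef / lam * (np.exp(-lam * t1) - upper)
    return float(dose_per_kg * terms)
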
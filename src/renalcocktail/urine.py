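"""Urine mass accounting: excreted amount, renal clearance, recovery, flow.

Amounts are in mg (concentration mg/L x volume ml / 1000); clearances
are reported in ml/min/kg.  Urine concentrations flagged below the LLOQ
contribute zero amount (conservative; the source study does not state
its handling).
"""

from __future__ import annotations

import numpy as np

from .design import UrineCollection
from .errors import InvalidCollectionError
from .units import l_h_kg_to_ml_min_kg

__all__ = ["cumulative_ae", "renal_clearance", "urinary_recovery", "urine_flow_rate"]


def _check_intervals(collection: UrineCollection) -> None:
    prev_end = -np.inf
    for iv in collection.intervals:
        if iv.t_end <= iv.t_start:
            raise InvalidCollectionError(
                f"interval ({iv.t_start}, {iv.t_end}) has nonpositive duration")
        if iv.t_start < prev_end:
            raise InvalidCollectionError(
                f"interval starting at {iv.t_start} overlaps the previous one")
        if iv.volume_ml < 0:
            raise InvalidCollectionError("urine volumes must be >= 0")
        prev_end = iv.t_end


def cumulative_ae(collection: UrineCollection, t_end: float = np.inf) -> float:
    """Cumulative amount excreted (mg) over intervals ending at or before t_end.

    Ae = sum_i conc_i x volume_i; censored (below-LLOQ) intervals count as
    zero amount.
    """
    _check_intervals(collection)
    total = 0.0
    for iv in collection.intervals:
        if iv.t_end <= t_end + 1e-9 and not iv.censored:
            total += iv.conc * iv.volume_ml / 1000.0
    return total


def renal_clearance(ae: float, auc: float, bw: float) -> float:
    """CL_R = Ae / AUC, per kg, in ml/min/kg.

    ae in mg, auc in mg*h/L (the plasma AUC over the matching interval:
    AUC(0, inf) for markers collected to completion, AUC(0, 48 h) for
    fluconazole), bw in kg.
    """
    if auc <= 0:
        raise ValueError(f"AUC must be positive, got {auc}")
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    cl_l_h_kg = (ae / auc) / bw
    return l_h_kg_to_ml_min_kg(cl_l_h_kg)


def urinary_recovery(ae: float, dose_per_kg: float, bw: float) -> tuple[float, bool]:
    """Fraction of the dose recovered in urine, as percent.

    Returns (recovery_percent, implausible) where the flag marks recovery
    above 100% (assay or volume error) without failing hard.
    """
    if dose_per_kg <= 0:
        raise ValueError(f"dose must be positive, got {dose_per_kg}")
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    frac = ae / (dose_per_kg * bw)
    return 100.0 * frac, frac > 1.0


def urine_flow_rate(collection: UrineCollection, bw: float) -> float:
    """Total voided volume over the collection span, in ml/kg/h."""
    _check_intervals(collection)
    if not collection.intervals:
        return 0.0
    duration = collection.intervals[-1].t_end - collection.intervals[0].t_start
    if duration <= 0:
        raise ValueError("collection duration must be positive")
    volume = sum(iv.volume_ml for iv in collection.intervals)
    return volume / (bw * duration)
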
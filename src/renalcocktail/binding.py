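"""Unbound-fraction estimation from ultrafiltration binding assays.

The unbound plasma fraction is fu = C_unbound / C_total, with the
ultrafiltrate concentration first corrected for nonspecific binding
(NSB) of the compound to the filtration device:

    NSB = (C_PBS,NF - C_PBS,F) / C_PBS,NF
    C_unbound = C_measured / (1 - NSB)

Negative apparent binding (fu marginally above 1, or negative NSB) is a
noise artefact and is clamped with an audit flag — this mirrors the
study's handling of PAH, whose apparent binding of -4.4% maps to fu = 1.
A single cohort-level fu per analyte (mean over levels x replicates) is
used downstream, as the assays run on pooled blank plasma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .design import BindingAssayData
from .errors import ConfigurationError

__all__ = ["BindingAssayResult", "unbound_fraction", "nsb", "correct_nsb", "assay_fu"]


@dataclass(frozen=True)
class BindingAssayResult:
    analyte: str
    fu_values: Tuple[float, ...]   # per level x replicate, post-clamp
    fu_mean: float
    fu_sd: float
    nsb_mean: float
    correction_applied: bool
    n_clamped: int


def unbound_fraction(c_unbound: float, c_total: float) -> tuple[float, bool]:
    """fu = C_unbound / C_total; values above 1 clamp to 1 with a flag."""
    if c_total <= 0:
        raise ValueError(f"total concentration must be positive, got {c_total}")
    if c_unbound < 0:
        raise ValueError(f"unbound concentration must be >= 0, got {c_unbound}")
    fu = c_unbound / c_total
    if fu > 1.0:
        return 1.0, True
    return fu, False


def nsb(c_pbs_nonfiltered: float, c_pbs_filtered: float) -> tuple[float, bool]:
    """Fraction lost to the device; negative values clamp to 0 with a flag."""
    if c_pbs_nonfiltered <= 0:
        raise ValueError("nonfiltered PBS concentration must be positive")
    value = (c_pbs_nonfiltered - c_pbs_filtered) / c_pbs_nonfiltered
    if value < 0.0:
        return 0.0, True
    return value, False


def correct_nsb(c_measured: float, nsb_fraction: float) -> float:
    """Recover the true ultrafiltrate concentration: C = C_measured / (1 - NSB)."""
    if not 0.0 <= nsb_fraction < 1.0:
        raise ValueError(f"NSB must lie in [0, 1), got {nsb_fraction}")
    return c_measured / (1.0 - nsb_fraction)


def assay_fu(data: BindingAssayData, apply_nsb_correction: bool = True) -> BindingAssayResult:
    """Cohort-level fu from a full assay (levels x replicates + controls).

    Per replicate the ultrafiltrate is NSB-corrected (using the mean NSB
    across all controls) and divided by its paired total.  The correction
    is skipped whenever the mean apparent NSB is <= 0 — the no-binding
    case where the study judged NSB determination unnecessary.
    """
    if data.c_total.size == 0:
        raise ConfigurationError("binding assay needs at least one level and replicate")
    if apply_nsb_correction:
        if data.c_pbs_nonfiltered.size == 0 or data.c_pbs_filtered.size == 0:
            raise ConfigurationError(
                "NSB correction requested but PBS filter controls are missing")
        nsb_values = [
            nsb(nf, f)[0] if (nf - f) / nf >= 0 else (nf - f) / nf
            for nf, f in zip(data.c_pbs_nonfiltered.ravel(),
                             data.c_pbs_filtered.ravel())
        ]
        nsb_mean = float(np.mean(nsb_values))
    else:
        nsb_mean = 0.0
    applied = apply_nsb_correction and nsb_mean > 0.0
    effective_nsb = nsb_mean if applied else 0.0

    fus = []
    n_clamped = 0
    for c_tot, c_uf in zip(data.c_total.ravel(), data.c_ultrafiltrate.ravel()):
        corrected = correct_nsb(c_uf, effective_nsb)
        fu, clamped = unbound_fraction(corrected, c_tot)
        fus.append(fu)
        n_clamped += int(clamped)
    fus = np.asarray(fus)
    return BindingAssayResult(
        analyte=data.analyte,
        fu_values=tuple(float(f) for f in fus),
        fu_mean=float(fus.mean()),
        fu_sd=float(fus.std(ddof=1)) if fus.size > 1 else 0.0,
        nsb_mean=max(nsb_mean, 0.0),
        correction_applied=applied,
        n_clamped=n_clamped,
    )
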
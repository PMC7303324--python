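"""Noncompartmental AUC by the linear-up / log-down trapezoidal rule.

Used for the fluconazole 0-48 h clearance interval, where the terminal
phase is too slow for the urine collection window and the compartmental
AUC(0, inf) is not the right denominator.  Rising (or flat, or zero-
touching) segments use the linear trapezoid; strictly falling segments
with positive endpoints use the log trapezoid, which is exact for
monoexponential decay.  No extrapolation beyond the last sample is
implemented: the study sampled at 48 h, so t_end must be an observation
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["AUCResult", "auc_0_t"]


@dataclass(frozen=True)
class AUCResult:
    t_start: float
    t_end: float
    value: float
    method: str
    segments: Tuple[float, ...]  # per-segment contributions, sum to value


def auc_0_t(times, concs, t_end: float) -> AUCResult:
    """AUC from the first observation to t_end (linear up / log down).

    times must be strictly increasing; concs non-negative; t_end must
    coincide with an observation time (no interpolation).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.size != c.size or t.size < 2:
        raise ValueError("need matching 1-d arrays of at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("negative concentrations are not allowed")
    idx = np.flatnonzero(np.isclose(t, t_end, rtol=0.0, atol=1e-9))
    if idx.size == 0:
        raise ValueError(
            f"t_end={t_end} is not an observation time; interpolation is not supported")
    end = int(idx[0])

    segs = []
    for i in range(end):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c0 > 0 and c1 > 0:
            segs.append((c0 - c1) / np.log(c0 / c1) * dt)  # log-down
        else:
            segs.append(0.5 * (c0 + c1) * dt)  # linear (up, flat, or zero)
    return AUCResult(t_start=float(t[0]), t_end=float(t[end]),
                     value=float(sum(segs)), method="linear_up_log_down",
                     segments=tuple(float(s) for s in segs))
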
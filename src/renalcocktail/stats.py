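"""Cohort descriptive statistics and the exact Wilcoxon signed-rank test.

With six to eight animals per comparison a normal approximation to the
signed-rank null is indefensible, so the two-sided p-value is computed
by full enumeration of all 2^n sign assignments of the midranked
absolute differences — exact also in the presence of ties.  Zero
differences are dropped beforehand (classic Wilcoxon convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

__all__ = ["summarize", "wilcoxon_exact", "PairedComparison"]


def summarize(values: Sequence[float]) -> Tuple[float, float, int]:
    """(mean, sample SD with n-1 denominator, n); SD is 0 for n == 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


@dataclass(frozen=True)
class PairedComparison:
    quantity: str
    W: float                 # sum of positive-signed ranks
    p_value: float           # exact two-sided
    n: int                   # pairs supplied
    n_effective: int         # after zero-difference removal
    significant: bool        # at alpha
    alpha: float
    degenerate: bool         # all differences zero


def wilcoxon_exact(x: Sequence[float], y: Sequence[float],
                   quantity: str = "", alpha: float = 0.05) -> PairedComparison:
    """Exact two-sided Wilcoxon signed-rank test on paired samples.

    Differences d = x - y; zeros dropped; |d| midranked; W = sum of ranks
    with d > 0.  The two-sided p doubles the smaller tail probability of
    W under the 2^n equiprobable sign assignments, capped at 1.  The
    all-zero case is flagged degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d sequences")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = x - y
    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff == 0:
        return PairedComparison(quantity=quantity, W=0.0, p_value=1.0,
                                n=x.size, n_effective=0, significant=False,
                                alpha=alpha, degenerate=True)
    d = d[nonzero]
    ranks = rankdata(np.abs(d))  # midranks under ties
    w_obs = float(ranks[d > 0].sum())
    if n_eff > 20:
        raise ValueError(
            f"exact enumeration over 2^{n_eff} sign patterns refused; "
            "this test targets small paired cohorts")

    # distribution of W over all sign assignments
    w_values = np.zeros(2 ** n_eff)
    for i, signs in enumerate(product((0.0, 1.0), repeat=n_eff)):
        w_values[i] = float(np.dot(signs, ranks))
    total = w_values.size
    p_lower = np.count_nonzero(w_values <= w_obs + 1e-9) / total
    p_upper = np.count_nonzero(w_values >= w_obs - 1e-9) / total
    p = min(1.0, 2.0 * min(p_lower, p_upper))
    return PairedComparison(quantity=quantity, W=w_obs, p_value=p,
                            n=x.size, n_effective=n_eff,
                            significant=p <= alpha, alpha=alpha,
                            degenerate=False)
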
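"""Partition of renal function into filtration, flow, secretion, reabsorption.

The core calculus of the marker-cocktail approach:

* GFR  = CL_TOT of the freely filtered, unbound, unsecreted marker (iohexol)
* ERPF = CL_R of the near-completely extracted marker (PAH)
* FF   = 100 x GFR / ERPF
* CL_fil(a)  = fu(a) x GFR            (filtration clearance of the unbound drug)
* secretion(a)    = CL_R(a) - CL_fil(a)
* reabsorption(a) = CL_fil(a) - CL_R(a)
* CL_NR(a)   = CL_TOT(a) - CL_R(a)

Every clearance is carried per kg and indexed to body surface area via
the species-appropriate rule (Meeh for pigs, Du Bois for humans).
Cohort rows are means +/- SD of per-animal values — never ratios of the
cohort means, which differ by a Jensen gap of a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["BodySize", "meeh_bsa", "dubois_bsa", "index_clearance",
           "partition", "SECRETION_MARKERS", "REABSORPTION_MARKERS"]

SECRETION_MARKERS = ("pah", "r_pindolol", "s_pindolol")
REABSORPTION_MARKERS = ("fluconazole",)


def meeh_bsa(bw: float) -> float:
    """Porcine body surface area (m^2) by the Meeh rule: 9 * BW^(2/3) dm^2."""
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    return 9.0 * bw ** (2.0 / 3.0) / 100.0


def dubois_bsa(bw: float, height_cm: float) -> float:
    """Human body surface area (m^2) by Du Bois: 0.007184 * BW^0.425 * H^0.725."""
    if bw <= 0 or height_cm <= 0:
        raise ValueError("body weight and height must be positive")
    return 0.007184 * bw ** 0.425 * height_cm ** 0.725


@dataclass(frozen=True)
class BodySize:
    """Body weight plus surface area under a stated rule."""

    bw: float
    bsa: float
    rule: str  # "meeh" | "dubois"
    height_cm: Optional[float] = None

    @classmethod
    def pig(cls, bw: float) -> "BodySize":
        return cls(bw=bw, bsa=meeh_bsa(bw), rule="meeh")

    @classmethod
    def human(cls, bw: float, height_cm: float) -> "BodySize":
        return cls(bw=bw, bsa=dubois_bsa(bw, height_cm), rule="dubois",
                   height_cm=height_cm)


def index_clearance(cl_per_kg: float, body: BodySize) -> dict:
    """Index a per-kg clearance to absolute (ml/min) and per-m^2 terms.

    absolute = cl_per_kg x BW; per_m2 = absolute / BSA, so the identity
    per_kg x BW == per_m2 x BSA holds exactly.
    """
    absolute = cl_per_kg * body.bw
    return {
        "per_kg": cl_per_kg,
        "per_m2": absolute / body.bsa,
        "absolute": absolute,
    }


def partition(per_animal: pd.DataFrame, fu: Dict[str, float],
              gfr_marker: str = "iohexol", erpf_marker: str = "pah",
              secretion_markers: Sequence[str] = SECRETION_MARKERS,
              reabsorption_markers: Sequence[str] = REABSORPTION_MARKERS,
              ) -> pd.DataFrame:
    """Per-animal renal function profile from marker clearances.

    per_animal: one row per animal x analyte with columns
        animal_id, analyte, bw, cl_tot (ml/min/kg),
        cl_r (ml/min/kg; NaN for urine-excluded animals or unmeasured),
        excluded_from_urine (bool)
    fu: cohort-level unbound fraction per analyte (the GFR marker defaults
        to 1.0 — negligible protein binding is what qualifies it).

    Returns one row per animal x quantity with per-kg, per-m^2 and
    absolute values.  GFR is computed for every animal (plasma-only);
    urine-dependent quantities (ERPF, FF, secretion, reabsorption, CL_NR,
    CL_R) are NaN-skipped for excluded animals, reproducing the n=8
    plasma vs n=6 urine split of the source study.
    """
    required = {"animal_id", "analyte", "bw", "cl_tot", "cl_r", "excluded_from_urine"}
    missing = required - set(per_animal.columns)
    if missing:
        raise ConfigurationError(f"per_animal table lacks columns: {sorted(missing)}")
    analytes = set(per_animal["analyte"])
    if gfr_marker not in analytes:
        raise ConfigurationError(f"GFR marker {gfr_marker!r} absent from input")
    if erpf_marker not in analytes:
        raise ConfigurationError(f"ERPF marker {erpf_marker!r} absent from input")

    rows: List[dict] = []

    def emit(animal_id, body, quantity, analyte, value_per_kg):
        if value_per_kg is None or np.isnan(value_per_kg):
            return
        idx = index_clearance(value_per_kg, body)
        rows.append({
            "animal_id": animal_id, "quantity": quantity, "analyte": analyte,
            "per_kg": idx["per_kg"], "per_m2": idx["per_m2"],
            "absolute": idx["absolute"], "bw": body.bw, "bsa": body.bsa,
        })

    for animal_id, group in per_animal.groupby("animal_id", sort=True):
        body = BodySize.pig(float(group["bw"].iloc[0]))
        excluded = bool(group["excluded_from_urine"].iloc[0])
        by_analyte = group.set_index("analyte")

        gfr = float(by_analyte.loc[gfr_marker, "cl_tot"])
        emit(animal_id, body, "GFR", gfr_marker, gfr)

        if excluded:
            continue  # all remaining quantities need complete urine

        erpf = float(by_analyte.loc[erpf_marker, "cl_r"])
        emit(animal_id, body, "ERPF", erpf_marker, erpf)
        if erpf > 0 and not np.isnan(erpf):
            rows.append({
                "animal_id": animal_id, "quantity": "FF", "analyte": "",
                "per_kg": 100.0 * gfr / erpf, "per_m2": 100.0 * gfr / erpf,
                "absolute": np.nan, "bw": body.bw, "bsa": body.bsa,
            })

        for analyte in sorted(analytes):
            row = by_analyte.loc[analyte]
            fu_a = fu.get(analyte, 1.0 if analyte == gfr_marker else None)
            if fu_a is None:
                raise ConfigurationError(f"no unbound fraction supplied for {analyte!r}")
            cl_fil = fu_a * gfr
            emit(animal_id, body, "CL_fil", analyte, cl_fil)
            cl_r = float(row["cl_r"])
            cl_tot = float(row["cl_tot"])
            if not np.isnan(cl_r):
                emit(animal_id, body, "CL_R", analyte, cl_r)
                emit(animal_id, body, "CL_NR", analyte, cl_tot - cl_r)
                if analyte in secretion_markers:
                    emit(animal_id, body, "net_secretion", analyte, cl_r - cl_fil)
                if analyte in reabsorption_markers:
                    emit(animal_id, body, "net_reabsorption", analyte, cl_fil - cl_r)
    return pd.DataFrame(rows)


def cohort_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD (ddof=1) and n of per-animal values per quantity x analyte."""
    grouped = profile.groupby(["quantity", "analyte"], sort=True)
    out = grouped.agg(
        per_kg_mean=("per_kg", "mean"), per_kg_sd=("per_kg", lambda s: s.std(ddof=1)),
        per_m2_mean=("per_m2", "mean"), per_m2_sd=("per_m2", lambda s: s.std(ddof=1)),
        n=("per_kg", "size"),
    ).reset_index()
    return out
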
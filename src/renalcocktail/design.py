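"""Study design, domain records and the default porcine marker study.

The defaults encode the published 7-week-old-pig cocktail study: four
markers given as separate IV boluses (iohexol for GFR, PAH for
ERPF/anion secretion, racemic pindolol for cation secretion, fluconazole
for net reabsorption), 15 plasma samples over 72 h and interval urine
collection over 48 h.  Pindolol is handled as two independent analytes
(R and S isomers) dosed at the isomer fraction of the racemate, because
the isomers have fully separate kinetics and assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidDesignError
from .models import OneCompartmentParams, TwoCompartmentParams, Params
from .units import ml_min_kg_to_l_h_kg

ANALYTES = ("iohexol", "pah", "r_pindolol", "s_pindolol", "fluconazole")

# marker roles in the renal partition
ROLE_GFR = "iohexol"
ROLE_ERPF = "pah"


@dataclass(frozen=True)
class AnimalRecord:
    """One pig: identifier, body weight (kg) and exclusion flags."""

    animal_id: str
    bw: float
    excluded_from_urine: bool = False


@dataclass(frozen=True)
class StudyDesign:
    """Dosing, sampling schedule, urine grid and assay limits.

    doses_per_kg        mg/kg per analyte (pindolol already split by isomer)
    plasma_schedule     sampling times in h, starting at 0 (pre-dose)
    urine_interval_bounds  boundary times of the collection intervals (h)
    lloq                lower limit of quantification, mg/L per analyte
    isomer_fraction_R   R fraction in the dosed racemate
    """

    doses_per_kg: Dict[str, float]
    plasma_schedule: Tuple[float, ...]
    urine_interval_bounds: Tuple[float, ...]
    lloq: Dict[str, float]
    isomer_fraction_R: float = 0.5098

    def __post_init__(self):
        sched = np.asarray(self.plasma_schedule, dtype=float)
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise InvalidDesignError("plasma schedule must start at 0 and be strictly increasing")
        bounds = np.asarray(self.urine_interval_bounds, dtype=float)
        if np.any(np.diff(bounds) <= 0):
            raise InvalidDesignError("urine interval bounds must be strictly increasing")
        if any(d <= 0 for d in self.doses_per_kg.values()):
            raise InvalidDesignError("doses must be positive")
        if any(l <= 0 for l in self.lloq.values()):
            raise InvalidDesignError("LLOQs must be positive")
        if not 0 < self.isomer_fraction_R < 1:
            raise InvalidDesignError("isomer_fraction_R must lie in (0, 1)")

    @property
    def urine_intervals(self) -> List[Tuple[float, float]]:
        b = self.urine_interval_bounds
        return list(zip(b[:-1], b[1:]))


@dataclass(frozen=True)
class AnalyteTruth:
    """Ground-truth kinetics of one analyte for the simulator.

    params      structural disposition parameters (1- or 2-compartment)
    cl_renal    true renal clearance, L/h/kg (0 <= cl_renal <= params.CL)
    fu          true unbound plasma fraction
    nsb         true nonspecific binding of the ultrafiltration device
    """

    params: Params
    cl_renal: float
    fu: float
    nsb: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.cl_renal <= self.params.CL + 1e-12:
            raise InvalidDesignError("renal clearance must lie in [0, CL_TOT]")
        if not 0.0 <= self.fu <= 1.0 or not 0.0 <= self.nsb <= 1.0:
            raise InvalidDesignError("fu and nsb must lie in [0, 1]")


@dataclass(frozen=True)
class TrueParameterSet:
    """Ground truth for a whole simulated study."""

    analytes: Dict[str, AnalyteTruth]
    urine_flow: float = 2.03  # ml/kg/h

    def __post_init__(self):
        if self.urine_flow <= 0:
            raise InvalidDesignError("urine flow must be positive")


@dataclass
class PlasmaProfile:
    """Time-ordered plasma concentrations of one animal x analyte.

    concs are mg/L; censored marks records below the LLOQ (stored as
    simulated/measured, but flagged).  The t=0 pre-dose sample is zero
    by design and always censored.
    """

    animal_id: str
    analyte: str
    times: np.ndarray
    concs: np.ndarray
    lloq: float
    censored: np.ndarray
    dose_per_kg: float

    def n_quantified(self) -> int:
        return int((~self.censored).sum())


@dataclass
class UrineInterval:
    t_start: float
    t_end: float
    volume_ml: float
    conc: float  # mg/L of urine
    censored: bool = False


@dataclass
class UrineCollection:
    """Sequence of timed urine intervals for one animal x analyte."""

    animal_id: str
    analyte: str
    intervals: List[UrineInterval]


@dataclass
class BindingAssayData:
    """Ultrafiltration assay rows: spiked plasma plus PBS filter controls."""

    analyte: str
    levels: np.ndarray        # nominal spike concentrations
    c_total: np.ndarray       # shape (n_levels, n_replicates)
    c_ultrafiltrate: np.ndarray
    c_pbs_nonfiltered: np.ndarray
    c_pbs_filtered: np.ndarray


@dataclass
class StudyDataset:
    """Everything a simulated study produces, plus retained ground truth."""

    design: StudyDesign
    animals: List[AnimalRecord]
    plasma: Dict[Tuple[str, str], PlasmaProfile]
    urine: Dict[Tuple[str, str], UrineCollection]
    binding: Dict[str, BindingAssayData]
    truth: Optional[TrueParameterSet] = None
    animal_truth: Optional[Dict[Tuple[str, str], AnalyteTruth]] = None


# which structural model each analyte gets, as fixed in the source study
DEFAULT_MODEL_BY_ANALYTE = {
    "iohexol": "2cpt",
    "pah": "1cpt",
    "r_pindolol": "1cpt",
    "s_pindolol": "1cpt",
    "fluconazole": "2cpt",
}


def default_design() -> StudyDesign:
    """The pig study design: doses, 0-72 h plasma schedule, 48 h urine grid."""
    f_r = 0.5098
    return StudyDesign(
        doses_per_kg={
            "iohexol": 64.7,
            "pah": 10.0,
            "r_pindolol": 0.05 * f_r,
            "s_pindolol": 0.05 * (1.0 - f_r),
            "fluconazole": 0.5,
        },
        plasma_schedule=(
            0.0, 5 / 60, 15 / 60, 30 / 60, 45 / 60, 1.0,
            2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0,
        ),
        # actual collection times were not reported; an 8-interval grid over
        # 0-48 h is assumed and configurable
        urine_interval_bounds=(0.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0),
        lloq={
            "iohexol": 0.25,
            "pah": 0.25,
            "r_pindolol": 0.0002,  # 0.2 ng/ml
            "s_pindolol": 0.0002,
            "fluconazole": 0.1,
        },
        isomer_fraction_R=f_r,
    )


def default_truth() -> TrueParameterSet:
    """Ground truth built from the published cohort-mean parameters.

    Clearances (ml/min/kg -> L/h/kg): CL_TOT iohexol 4.12, PAH 31.53,
    S-pindolol 173.08, R-pindolol 54.20, fluconazole 0.45; CL_R PAH 9.51,
    S-pindolol 3.28, R-pindolol 1.34, fluconazole 0.32.  Iohexol is treated
    as fully renally cleared (GFR marker).  Volumes not printed for iohexol
    and PAH are physiologically plausible choices for a 7-week-old pig.
    """
    c = ml_min_kg_to_l_h_kg
    return TrueParameterSet(
        analytes={
            "iohexol": AnalyteTruth(
                params=TwoCompartmentParams(V1=0.11, CL=c(4.12), Q=0.15, V2=0.16),
                cl_renal=c(4.12), fu=1.0, nsb=0.0,
            ),
            "pah": AnalyteTruth(
                params=OneCompartmentParams(V=0.65, CL=c(31.53)),
                cl_renal=c(9.51), fu=1.0, nsb=0.0,
            ),
            "s_pindolol": AnalyteTruth(
                params=OneCompartmentParams(V=6.60, CL=c(173.08)),
                cl_renal=c(3.28), fu=0.62, nsb=0.0,
            ),
            "r_pindolol": AnalyteTruth(
                params=OneCompartmentParams(V=2.12, CL=c(54.20)),
                cl_renal=c(1.34), fu=0.19, nsb=0.0,
            ),
            "fluconazole": AnalyteTruth(
                params=TwoCompartmentParams(V1=0.70, CL=c(0.45), Q=0.1, V2=0.28),
                cl_renal=c(0.32), fu=0.89, nsb=0.20,
            ),
        },
        urine_flow=2.03,
    )


def perturbed_truth(truth: AnalyteTruth, factors: Dict[str, float]) -> AnalyteTruth:
    """Scale an analyte's clearances/volumes by per-animal log-normal factors.

    CL_TOT and the structural volumes each get their own factor; the renal
    fraction CL_R/CL_TOT is kept fixed so 0 <= CL_R <= CL_TOT holds for any
    draw.
    """
    p = truth.params
    f_cl = factors.get("CL", 1.0)
    f_v = factors.get("V", 1.0)
    if isinstance(p, OneCompartmentParams):
        new_p: Params = OneCompartmentParams(V=p.V * f_v, CL=p.CL * f_cl)
    else:
        f_q = factors.get("Q", 1.0)
        new_p = TwoCompartmentParams(V1=p.V1 * f_v, CL=p.CL * f_cl, Q=p.Q * f_q, V2=p.V2 * f_v)
    renal_fraction = truth.cl_renal / truth.params.CL
    return replace(truth, params=new_p, cl_renal=renal_fraction * new_p.CL)
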
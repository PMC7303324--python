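"""Canonical CSV dialects of the study and round-trip readers.

All files are UTF-8 CSV with a header row and '.' decimal:

* animals.csv  animal_id, bw_kg, excluded_from_urine
* plasma.csv   animal_id, analyte, time_h, conc_mg_l, censored, lloq_mg_l,
               dose_mg_per_kg
* urine.csv    animal_id, analyte, t_start_h, t_end_h, volume_ml,
               conc_mg_l, censored
* binding.csv  analyte, level, replicate, c_total, c_ultrafiltrate,
               c_pbs_nonfiltered, c_pbs_filtered
* truth.json   simulator ground truth (testing only)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .design import (
    AnimalRecord,
    BindingAssayData,
    PlasmaProfile,
    StudyDataset,
    StudyDesign,
    UrineCollection,
    UrineInterval,
    default_design,
)
from .models import OneCompartmentParams, TwoCompartmentParams


def animals_frame(dataset: StudyDataset) -> pd.DataFrame:
    return pd.DataFrame([
        {"animal_id": a.animal_id, "bw_kg": a.bw,
         "excluded_from_urine": a.excluded_from_urine}
        for a in dataset.animals
    ])


def plasma_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for (animal_id, analyte), prof in sorted(dataset.plasma.items()):
        for t, c, cen in zip(prof.times, prof.concs, prof.censored):
            rows.append({
                "animal_id": animal_id, "analyte": analyte, "time_h": t,
                "conc_mg_l": c, "censored": bool(cen), "lloq_mg_l": prof.lloq,
                "dose_mg_per_kg": prof.dose_per_kg,
            })
    return pd.DataFrame(rows)


def urine_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for (animal_id, analyte), coll in sorted(dataset.urine.items()):
        for iv in coll.intervals:
            rows.append({
                "animal_id": animal_id, "analyte": analyte,
                "t_start_h": iv.t_start, "t_end_h": iv.t_end,
                "volume_ml": iv.volume_ml, "conc_mg_l": iv.conc,
                "censored": bool(iv.censored),
            })
    return pd.DataFrame(rows)


def binding_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for analyte, assay in sorted(dataset.binding.items()):
        n_levels, n_reps = assay.c_total.shape
        for i in range(n_levels):
            for j in range(n_reps):
                rows.append({
                    "analyte": analyte, "level": assay.levels[i],
                    "replicate": j + 1,
                    "c_total": assay.c_total[i, j],
                    "c_ultrafiltrate": assay.c_ultrafiltrate[i, j],
                    "c_pbs_nonfiltered": assay.c_pbs_nonfiltered[i, j],
                    "c_pbs_filtered": assay.c_pbs_filtered[i, j],
                })
    return pd.DataFrame(rows)


def _params_to_dict(params) -> dict:
    d = dataclasses.asdict(params)
    d["model"] = "1cpt" if isinstance(params, OneCompartmentParams) else "2cpt"
    return d


def truth_dict(dataset: StudyDataset) -> dict:
    truth = dataset.truth
    if truth is None:
        return {}
    return {
        "urine_flow_ml_kg_h": truth.urine_flow,
        "analytes": {
            name: {
                "params": _params_to_dict(t.params),
                "cl_renal_l_h_kg": t.cl_renal,
                "fu": t.fu, "nsb": t.nsb,
            } for name, t in truth.analytes.items()
        },
    }


def write_dataset(dataset: StudyDataset, outdir) -> Dict[str, Path]:
    """Emit animals/plasma/urine/binding CSVs and truth.json under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("animals", animals_frame(dataset)),
                        ("plasma", plasma_frame(dataset)),
                        ("urine", urine_frame(dataset)),
                        ("binding", binding_frame(dataset))):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth_dict(dataset), indent=1))
    paths["truth"] = truth_path
    return paths


def read_dataset(indir, design: StudyDesign | None = None) -> StudyDataset:
    """Rebuild a StudyDataset from the CSV dialects (truth not restored)."""
    indir = Path(indir)
    design = design or default_design()
    animals_df = pd.read_csv(indir / "animals.csv")
    animals = [AnimalRecord(r.animal_id, float(r.bw_kg), bool(r.excluded_from_urine))
               for r in animals_df.itertuples()]

    plasma: Dict[Tuple[str, str], PlasmaProfile] = {}
    for (animal_id, analyte), g in pd.read_csv(indir / "plasma.csv").groupby(
            ["animal_id", "analyte"]):
        g = g.sort_values("time_h")
        plasma[(animal_id, analyte)] = PlasmaProfile(
            animal_id=animal_id, analyte=analyte,
            times=g["time_h"].to_numpy(float),
            concs=g["conc_mg_l"].to_numpy(float),
            lloq=float(g["lloq_mg_l"].iloc[0]),
            censored=g["censored"].to_numpy(bool),
            dose_per_kg=float(g["dose_mg_per_kg"].iloc[0]),
        )

    urine: Dict[Tuple[str, str], UrineCollection] = {}
    for (animal_id, analyte), g in pd.read_csv(indir / "urine.csv").groupby(
            ["animal_id", "analyte"]):
        g = g.sort_values("t_start_h")
        urine[(animal_id, analyte)] = UrineCollection(
            animal_id=animal_id, analyte=analyte,
            intervals=[UrineInterval(float(r.t_start_h), float(r.t_end_h),
                                     float(r.volume_ml), float(r.conc_mg_l),
                                     bool(r.censored))
                       for r in g.itertuples()],
        )

    binding: Dict[str, BindingAssayData] = {}
    for analyte, g in pd.read_csv(indir / "binding.csv").groupby("analyte"):
        levels = np.sort(g["level"].unique())
        pivot = {col: [] for col in ("c_total", "c_ultrafiltrate",
                                     "c_pbs_nonfiltered", "c_pbs_filtered")}
        for lvl in levels:
            sub = g[g["level"] == lvl].sort_values("replicate")
            for col in pivot:
                pivot[col].append(sub[col].to_numpy(float))
        binding[analyte] = BindingAssayData(
            analyte=analyte, levels=np.asarray(levels, dtype=float),
            **{col: np.vstack(vals) for col, vals in pivot.items()},
        )

    return StudyDataset(design=design, animals=animals, plasma=plasma,
                        urine=urine, binding=binding, truth=None)
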
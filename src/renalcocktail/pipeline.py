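"""End-to-end study analysis: fits -> urine clearances -> binding -> partition.

This module strings the per-stage operations into the full analysis a
study would run, and renders the three cohort tables:

* table1 — per-analyte AUC, Ae, CL_TOT, CL_R, CL_NR, urinary recovery
  (urine-complete animals only, as in the source cohort's n=6 columns)
* table2 — the renal function profile (GFR, ERPF, FF, net secretion,
  net reabsorption) per kg and per m^2
* table3 — plasma-only PK parameters (Vss, CL_TOT, Ke, T1/2, fu), all
  animals

Fluconazole's renal clearance divides Ae over 48 h by the
noncompartmental AUC(0-48 h) (linear-up/log-down, with a log
back-extrapolated bolus C0 at t=0); the other markers use the
compartmental AUC(0-inf) = dose/CL.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .binding import BindingAssayResult, assay_fu
from .design import DEFAULT_MODEL_BY_ANALYTE, StudyDataset
from .errors import PipelineOrderError
from .fitting import derive_secondary, exclude_bloq, fit_profile
from .models import OneCompartmentParams
from .nca import auc_0_t
from .partition import cohort_summary, partition
from .stats import summarize, wilcoxon_exact
from .units import l_h_kg_to_ml_min_kg
from .urine import cumulative_ae, renal_clearance, urinary_recovery

__all__ = ["fit_all", "urine_clearances", "binding_results",
           "run_study_analysis", "render_tables"]

NCA_CLR_ANALYTES = ("fluconazole",)  # Ae/AUC(0-48h) instead of AUC(0-inf)
NCA_WINDOW_H = 48.0


def fit_all(dataset: StudyDataset,
            model_by_analyte: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Fit every animal x analyte profile; one row each with secondary params."""
    models = dict(DEFAULT_MODEL_BY_ANALYTE)
    if model_by_analyte:
        models.update(model_by_analyte)
    bw = {a.animal_id: a.bw for a in dataset.animals}
    rows = []
    for (animal_id, analyte), profile in sorted(dataset.plasma.items()):
        filtered, n_removed = exclude_bloq(profile)
        fit = fit_profile(filtered, models[analyte])
        sec = derive_secondary(fit, profile.dose_per_kg)
        p = fit.params
        rows.append({
            "animal_id": animal_id, "analyte": analyte, "model": fit.model,
            "bw": bw[animal_id],
            "V1": p.V if isinstance(p, OneCompartmentParams) else p.V1,
            "V2": np.nan if isinstance(p, OneCompartmentParams) else p.V2,
            "Q": np.nan if isinstance(p, OneCompartmentParams) else p.Q,
            "CL_l_h_kg": p.CL,
            "cl_tot": l_h_kg_to_ml_min_kg(p.CL),
            "Ke": sec.Ke, "T_half_el": sec.T_half_el, "Vss": sec.Vss,
            "AUC_0_inf": sec.AUC_0_inf,
            "sigma": fit.sigma, "converged": fit.converged,
            "n_observations": fit.n_observations, "n_bloq_removed": n_removed,
        })
    return pd.DataFrame(rows)


def _nca_auc_48(dataset: StudyDataset, animal_id: str, analyte: str) -> float:
    """Observed-data AUC(0-48 h) with a log back-extrapolated bolus C0."""
    profile = dataset.plasma[(animal_id, analyte)]
    filtered, _ = exclude_bloq(profile)
    t, c = filtered.times, filtered.concs
    if t.size >= 2 and t[0] > 0 and c[0] > c[1] > 0:
        # log-linear back-extrapolation from the first two quantified points
        slope = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
        c0 = float(np.exp(np.log(c[0]) - slope * t[0]))
    else:
        c0 = float(c[0])
    t = np.concatenate([[0.0], t])
    c = np.concatenate([[c0], c])
    return auc_0_t(t, c, NCA_WINDOW_H).value


def urine_clearances(dataset: StudyDataset, fits: pd.DataFrame) -> pd.DataFrame:
    """Per animal x analyte: Ae, CL_R, urinary recovery.

    Animals flagged excluded-from-urine are dropped entirely, mirroring
    the exclusion of leaked urine bags from every clearance calculation.
    """
    fit_idx = fits.set_index(["animal_id", "analyte"])
    bw = {a.animal_id: a.bw for a in dataset.animals}
    excluded = {a.animal_id for a in dataset.animals if a.excluded_from_urine}
    rows = []
    for (animal_id, analyte), coll in sorted(dataset.urine.items()):
        if animal_id in excluded:
            continue
        profile = dataset.plasma[(animal_id, analyte)]
        if analyte in NCA_CLR_ANALYTES:
            filtered, _ = exclude_bloq(profile)
            if not np.any(np.isclose(filtered.times, NCA_WINDOW_H)):
                # the 48 h sample fell below the LLOQ: the stated NCA
                # method has no endpoint, so this animal contributes no
                # CL_R for this analyte (no extrapolation)
                continue
            ae = cumulative_ae(coll, NCA_WINDOW_H)
            auc = _nca_auc_48(dataset, animal_id, analyte)
        else:
            ae = cumulative_ae(coll)
            auc = float(fit_idx.loc[(animal_id, analyte), "AUC_0_inf"])
        cl_r = renal_clearance(ae, auc, bw[animal_id])
        recovery, implausible = urinary_recovery(ae, profile.dose_per_kg, bw[animal_id])
        rows.append({
            "animal_id": animal_id, "analyte": analyte, "bw": bw[animal_id],
            "ae_mg": ae, "auc": auc, "cl_r": cl_r,
            "recovery_pct": recovery, "recovery_implausible": implausible,
        })
    return pd.DataFrame(rows)


def binding_results(dataset: StudyDataset) -> Dict[str, BindingAssayResult]:
    """Cohort-level fu per assayed analyte (NSB-corrected where needed)."""
    return {analyte: assay_fu(assay) for analyte, assay in
            sorted(dataset.binding.items())}


def run_study_analysis(dataset: StudyDataset,
                       model_by_analyte: Optional[Dict[str, str]] = None) -> dict:
    """Full pipeline; returns fits, urine table, fu map, profile and summary."""
    fits = fit_all(dataset, model_by_analyte)
    urine = urine_clearances(dataset, fits)
    binding = binding_results(dataset)
    # iohexol needs no binding correction (negligible protein binding)
    fu = {"iohexol": 1.0}
    fu.update({analyte: res.fu_mean for analyte, res in binding.items()})

    excluded = {a.animal_id for a in dataset.animals if a.excluded_from_urine}
    urine_idx = urine.set_index(["animal_id", "analyte"])["cl_r"]
    per_animal = fits[["animal_id", "analyte", "bw", "cl_tot"]].copy()
    per_animal["cl_r"] = [
        urine_idx.get((r.animal_id, r.analyte), np.nan)
        for r in per_animal.itertuples()
    ]
    per_animal["excluded_from_urine"] = per_animal["animal_id"].isin(excluded)

    profile = partition(per_animal, fu)
    return {
        "fits": fits,
        "urine": urine,
        "binding": binding,
        "fu": fu,
        "per_animal": per_animal,
        "profile": profile,
        "summary": cohort_summary(profile),
    }


def _mean_sd_n(series) -> dict:
    mean, sd, n = summarize(series)
    return {"mean": mean, "sd": sd, "n": n}


def render_tables(results: dict, outdir, seed: Optional[int] = None,
                  config: Optional[dict] = None) -> Dict[str, Path]:
    """Write table1/table2/table3 CSVs and a JSON run log under outdir."""
    for key in ("fits", "urine", "profile", "summary"):
        if key not in results or results[key] is None:
            raise PipelineOrderError(
                f"stage output {key!r} is missing; run run_study_analysis first")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fits, urine = results["fits"], results["urine"]
    summary = results["summary"]

    # table 1 — clearance calculus inputs, urine-complete animals only
    t1_rows = []
    urine_animals = set(urine["animal_id"])
    for analyte, g in fits.groupby("analyte", sort=True):
        g6 = g[g["animal_id"].isin(urine_animals)]
        u = urine[urine["analyte"] == analyte]
        row = {"analyte": analyte}
        for label, series in (("AUC_0_inf", g6["AUC_0_inf"]),
                              ("CL_TOT", g6["cl_tot"])):
            s = _mean_sd_n(series)
            row.update({f"{label}_mean": s["mean"], f"{label}_sd": s["sd"]})
        if len(u):
            for label, series in (("Ae_mg", u["ae_mg"]), ("CL_R", u["cl_r"]),
                                  ("recovery_pct", u["recovery_pct"])):
                s = _mean_sd_n(series)
                row.update({f"{label}_mean": s["mean"], f"{label}_sd": s["sd"]})
            merged = g6.merge(u, on=["animal_id", "analyte"])
            clnr = merged["cl_tot"] - merged["cl_r"]
            s = _mean_sd_n(clnr)
            row.update({"CL_NR_mean": s["mean"], "CL_NR_sd": s["sd"]})
            row["n"] = len(u)
        else:
            row["n"] = len(g6)
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    # table 2 — renal function profile per kg and per m^2
    table2 = summary[summary["quantity"].isin(
        ["GFR", "ERPF", "FF", "net_secretion", "net_reabsorption"])].copy()

    # table 3 — plasma-only PK parameters, all animals
    t3_rows = []
    fu = results["fu"]
    for analyte, g in fits.groupby("analyte", sort=True):
        row = {"analyte": analyte, "fu": fu.get(analyte, np.nan), "n": len(g)}
        for label, series in (("Vss", g["Vss"]), ("CL_TOT", g["cl_tot"]),
                              ("Ke", g["Ke"]), ("T_half_el", g["T_half_el"])):
            s = _mean_sd_n(series)
            row.update({f"{label}_mean": s["mean"], f"{label}_sd": s["sd"]})
        t3_rows.append(row)
    table3 = pd.DataFrame(t3_rows)

    # paired isomer comparisons on the stereoselective parameters
    comparisons = []
    for param in ("cl_tot", "Vss", "Ke", "T_half_el"):
        wide = fits.pivot(index="animal_id", columns="analyte", values=param)
        if {"s_pindolol", "r_pindolol"} <= set(wide.columns):
            comp = wilcoxon_exact(wide["s_pindolol"].to_numpy(),
                                  wide["r_pindolol"].to_numpy(),
                                  quantity=f"{param} S vs R pindolol")
            comparisons.append({
                "quantity": comp.quantity, "W": comp.W, "p_value": comp.p_value,
                "n_effective": comp.n_effective, "significant": comp.significant,
            })

    paths = {}
    for name, frame in (("table1", table1), ("table2", table2),
                        ("table3", table3),
                        ("isomer_comparisons", pd.DataFrame(comparisons))):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path

    n_animals = len(set(fits["animal_id"]))
    log = {
        "seed": seed,
        "config": config or {},
        "n_animals": n_animals,
        "n_urine_complete": len(urine_animals),
        "excluded_from_urine": sorted(set(fits["animal_id"]) - urine_animals),
        "fu": {k: float(v) for k, v in fu.items()},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=1, sort_keys=True))
    paths["run_log"] = log_path
    return paths
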
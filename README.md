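# renalcocktail

Decomposition of renal function from an intravenous cocktail of exogenous
renal markers, for pharmacokineticists working with the growing pig as a
translational model of human renal drug excretion.

A single co-administration of four markers characterises each renal
elimination process separately:

| Marker | Process | Estimator |
| --- | --- | --- |
| iohexol | glomerular filtration rate (GFR) | total plasma clearance CL_TOT |
| p-aminohippuric acid (PAH) | effective renal plasma flow (ERPF), net anion secretion | renal clearance CL_R |
| R-/S-pindolol | net cation secretion (stereoselective) | CL_R per isomer |
| fluconazole | net tubular reabsorption | CL_R over 0–48 h |

From per-animal marker clearances the package computes

```
GFR  = CL_TOT(iohexol)                 FF (%) = 100 · GFR / ERPF
ERPF = CL_R(PAH)                       CL_fil(a) = fu(a) · GFR
CL_R = Ae / AUC                        CL_NR(a)  = CL_TOT(a) − CL_R(a)
net secretion(a)    = CL_R(a) − CL_fil(a)
net reabsorption(a) = CL_fil(a) − CL_R(a)
```

with Ae the cumulative amount excreted in urine, AUC the plasma exposure
(compartmental AUC₀→∞ = dose/CL, or the linear-up/log-down trapezoidal
AUC₀→₄₈ₕ for fluconazole), and fu the unbound plasma fraction from
ultrafiltration assays corrected for nonspecific device binding,
fu = (C_uf / (1 − NSB)) / C_total.  Clearances are indexed per kg body
weight and per m² body surface area (Meeh rule 9·BW^(2/3) dm² for pigs,
Du Bois for humans).

Because the study's raw per-animal data are not public, the package ships a
synthetic cohort generator (`renalcocktail.simulate`) that reproduces the
stated study world — IV bolus kinetics at the published cohort parameters,
the 0–72 h sampling schedule, 48 h interval urine collection, multiplicative
assay noise, LLOQ censoring and occasional urine-bag leakage — with the
ground truth retained so every downstream stage is testable.

## Worked example

```python
from renalcocktail import generate_cohort, simulate_study
from renalcocktail.pipeline import run_study_analysis

cohort = generate_cohort(8, bw_mean=9.75, bw_sd=1.61, seed=1)
dataset = simulate_study(cohort, noise_cv=0.10, between_animal_cv=0.15,
                         leakage_prob=0.25, seed=2)
results = run_study_analysis(dataset)
s = results["summary"].set_index(["quantity", "analyte"])
print(s.loc[("GFR", "iohexol"), ["per_kg_mean", "per_kg_sd", "n"]])
```

Running the numbered drivers reproduces the full analysis narrative:

```
python analysis/01_simulate_cohort.py      # virtual pigs -> results/simulated/
python analysis/02_fit_plasma_models.py    # per-animal compartmental fits
python analysis/03_partition_renal_function.py
python analysis/04_report_tables.py        # cohort tables + isomer tests
```

A representative run (seed 20200612, 8 pigs, 2 urine-bag leakages) prints

```
GFR: 4.26 +/- 0.47 ml/min/kg | 99.7 +/- 14.4 ml/min/m^2 (n=8)
ERPF: 9.28 +/- 0.98 ml/min/kg | 221.4 +/- 24.0 ml/min/m^2 (n=6)
FF %: 47.09 +/- 6.16
PAH net secretion: 5.02 +/- 1.06 ml/min/kg
fluconazole net reabsorption: 3.69 +/- 0.39 ml/min/kg
```

i.e. the virtual cohort recovers the generating physiology (true GFR
4.12 ml/min/kg, ERPF 9.51 ml/min/kg) within sampling noise, with leaked
animals contributing plasma-only endpoints.  The isomer report applies the
exact (enumeration) Wilcoxon signed-rank test; with eight animals the
smallest attainable two-sided p is 1/128.

The same stages are exposed as a CLI: `renal-cocktail simulate | fit |
partition | report` (see `--help`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch each run: the four nonrenal-clearance identities
CL_TOT − CL_R through the partition calculus; the Meeh and Du Bois
body-surface-area conversions of the cohort-mean GFR; the unbound fraction
of a no-binding ultrafiltration assay; and the mean fitted iohexol clearance
over 200 simulated pigs at 10% proportional noise, and writes them as JSON.
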
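# Methods

## Disposition models and units

All analytes are modelled as linear IV-bolus systems.  One-compartment:
C(t) = (D/V)·e^(−ke·t), ke = CL/V.  Two-compartment in the clearance
parameterisation (V1, CL, Q, V2), with micro constants k10 = CL/V1,
k12 = Q/V1, k21 = Q/V2 and macro constants A, B, α, β derived on demand
(α, β roots of s² − (k10+k12+k21)s + k10·k21).  The clearance
parameterisation is canonical because clearances and volumes are the
physiologically reported quantities; macro constants are never stored.
V_ss for the two-compartment model is defined as V1 + V2 (the moment
definition D·AUMC/AUC² coincides for IV bolus linear systems), and the
reported elimination rate constant Ke is the terminal rate β.

Internal units are hours, mg/L (≡ µg/ml), L/kg and L/h/kg; doses in
mg/kg.  Analytes assayed in ng/ml (pindolol isomers) are converted on
ingest; clearances are reported in ml/min/kg.  All converters live in
`renalcocktail.units`.

## Fitting

Each animal × analyte profile is fitted individually (no mixed-effects
pooling — cohorts of 6–8 are summarised as mean ± SD).  The
multiplicative error model is implemented as least squares on
log-concentrations, Σ(ln C_obs − ln C_pred)², the maximum-likelihood
equivalent of proportional error up to a constant.  Optimisation runs in
log-parameter space (Levenberg–Marquardt, xtol/ftol/gtol 1e−12), which
enforces positivity without constraint machinery and makes the fit
deterministic for fixed inputs.  Initial estimates come from curve
stripping: a log-linear regression gives (ke, C0) for the one-compartment
model; for two compartments the terminal third of the points gives
(β, B) and a residual peel of the early points gives (α, A), then macro
→ micro algebra gives the starting (V1, CL, Q, V2).  Model structure is
fixed per analyte (iohexol, fluconazole: 2-compartment; PAH, pindolol
isomers: 1-compartment), overridable by configuration; no per-animal
model selection is performed.

Records below the LLOQ are excluded before fitting (0.25 µg/ml iohexol
and PAH, 0.2 ng/ml pindolol isomers, 0.1 µg/ml fluconazole), as is the
pre-dose t = 0 sample.  A 1-compartment fit requires ≥ 3 quantified
points, a 2-compartment fit ≥ 5.

## Clearance calculus

CL_R = Ae/AUC with Ae = Σ conc_i × volume_i over the timed urine
intervals.  For markers whose plasma decays within the collection window
the denominator is the compartmental AUC₀→∞ = dose/CL; for fluconazole
(terminal half-life ≈ 26 h versus a 48 h collection) Ae over 48 h is
divided by the noncompartmental AUC₀→₄₈ₕ using the linear-up/log-down
trapezoid, with a log back-extrapolated bolus C0 inserted at t = 0
(log-linear through the first two quantified points).  Equal or
zero-touching segment endpoints use the linear rule (the log form is
0/0).  λz extrapolation to infinity is deliberately absent: the 48 h
endpoint must be an observed, quantified sample.  When noise pushes the
48 h fluconazole sample below the LLOQ, that animal's fluconazole CL_R is
treated as unobtainable by the stated method and dropped (no
extrapolation), which can reduce the fluconazole n below the urine-complete
n.

Urine concentrations below the LLOQ contribute zero amount
(conservative; flagged).  Animals with urine-bag leakage are excluded
from every urine-dependent quantity but retained for plasma-only
parameters — the n = 8 plasma versus n = 6 urine split.

## Protein binding

fu = C_unbound/C_total from ultrafiltration, with the ultrafiltrate
first corrected for nonspecific device binding:
C = C_measured/(1 − NSB), NSB = (C_PBS,NF − C_PBS,F)/C_PBS,NF.  The
correction is skipped when the mean apparent NSB ≤ 0 (the PAH case —
no binding, so no device correction is needed), and negative apparent
binding clamps to fu = 1 with an audit flag.  A single cohort-level fu
per analyte (mean over 3 levels × 3 replicates on pooled blank plasma)
feeds the partition; fu of iohexol is fixed at 1 (negligible protein
binding is what qualifies a GFR marker).

## Partition and indexing

GFR = CL_TOT(iohexol); ERPF = CL_R(PAH); FF = 100·GFR/ERPF;
CL_fil(a) = fu(a)·GFR; net secretion = CL_R − CL_fil; net reabsorption
= CL_fil − CL_R; CL_NR = CL_TOT − CL_R.  Secretion and reabsorption are
the same quantity with opposite sign; both are reported only for their
respective marker roles.  BSA: Meeh 9·BW^(2/3) dm² for pigs, Du Bois
0.007184·BW^0.425·H^0.725 for human comparisons; per_kg·BW = per_m²·BSA
is an identity of the indexing, not an approximation.  Cohort rows are
means ± SD (n−1) of per-animal values.  Recomputing table cells from
printed group means instead reproduces them only to within a
ratio-of-means vs mean-of-ratios (Jensen) gap of ≲ 3%, which the test
suite encodes as a consistency bound, not a target.

## Exact Wilcoxon signed-rank test

Paired isomer comparisons use full enumeration of the 2^n sign
assignments of the midranked |differences| — exact also under ties —
with zero differences dropped and the two-sided p doubled from the
smaller tail and capped at 1.  At n = 6 the attainable two-sided levels
are discrete; the largest ≤ 0.05 is 2/64 = 0.03125.  Enumeration is
refused above n = 20 (this is a small-cohort tool).

## Synthetic cohort: what it emulates and what it does not

The generator's defaults are the stated study world: 8 pigs of
9.75 ± 1.61 kg (normal, truncated at ±3 SD), doses 64.7 / 10 / 0.05 /
0.5 mg/kg (pindolol split 50.98 : 49.02 into R and S isomers, simulated
as independent analytes), the 15-point 0–72 h plasma schedule, urine
flow 2.03 ml/kg/h, 10% multiplicative plasma noise, 15% log-normal
between-animal variability applied to clearances and volumes with the
renal fraction held fixed (so 0 ≤ CL_R ≤ CL_TOT by construction), and a
25% per-animal urine-leakage probability (2 of 8 observed).  Urinary
amounts are mass-balance exact before noise: Ae(t1,t2) =
CL_R,true·AUC_true(t1,t2)·BW, so the noise-free round trip recovers the
generating clearances identically and any interval grid is valid.  The
actual collection times were not reported; the default grid
0,2,4,8,12,24,36,48 h is an assumption and configurable.

Ground-truth kinetics use the published cohort means; volumes not
printed for iohexol and PAH were chosen once as physiologically
realistic for a 7-week-old pig and not revisited: iohexol V1 = 0.11,
V2 = 0.16 L/kg (≈ extracellular water), Q = 0.15 L/h/kg; PAH
V = 0.65 L/kg (peak ≈ 15 µg/ml, below the tubular-secretion saturation
range); fluconazole V1 = 0.70, V2 = 0.28 L/kg (V_ss = 0.98 as printed),
Q = 0.1 L/h/kg.  These choices reproduce the printed terminal rates
where printed (fluconazole β = 0.0269 h⁻¹, T½ 25.7 h).  Pindolol CL_TOT
and V are the all-animal (plasma-only) estimates.

The simulator does not emulate: assay-batch effects or drift,
within-animal physiological variation over the 72 h (clearances are
constant), urine pH effects on reabsorption, PAH acetylation/metabolite
kinetics (mean renal acetylation is taken as 0%), incomplete bladder
emptying, or correlated between-animal parameters.  A green end-to-end
test therefore establishes correctness of the calculus and estimators
under the stated error model, not robustness to structural
misspecification.

## Numerical choices and degenerate inputs

α = β (coincident exponentials) raises an error rather than switching to
the repeated-root form — the case has measure zero in the clearance
parameterisation.  Q → 0 degenerates gracefully to the one-compartment
curve.  fu > 1 and NSB < 0 clamp with flags; recovery > 100% flags
without failing.  Fully censored profiles, overlapping urine intervals,
missing marker roles and missing NSB controls raise typed errors.
Simulation, fitting and reporting are bit-reproducible for a fixed seed;
all randomness flows from `numpy.random.default_rng(seed)`.

## Known limitations

Per-animal raw data of the source cohort are unavailable, so printed
cohort means are reproducible only through identities and deterministic
conversions, or statistically through simulation.  The Friis
extraction-ratio variant of FF (GFR/(CL_R/E_PAH)) is out of scope —
E_PAH was not measured.  The exact objective used by the original
commercial fitting software is unstated; log-least-squares is the
reproducible equivalent, and differences are within reported rounding.
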
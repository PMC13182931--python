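# dietrisk

Nutritional epidemiology for dialysis cohorts: estimate **nonlinear
associations between time-averaged dietary nutrient intake and all-cause
mortality**, and extract, per nutrient, the intake range associated with a
hazard ratio below 1 — stratified by baseline serum-albumin tertile.

The package is aimed at biostatisticians and nephrology researchers working
with longitudinal registry data from peritoneal-dialysis (PD) programs:
irregular quarterly visits, 3-day dietary records with whole-record
missingness, routine serum chemistry with per-feature missingness, and
censoring from transplantation, modality transfer or loss to follow-up.
Because such registries are rarely public, the package ships a
**synthetic-cohort generator** with known ground-truth diet effects, so every
stage of the analysis is testable end to end.

## The model

For patient *i* with follow-up time *T·i*, death indicator *δ·i*,
time-averaged nutrient intake *x·i* and confounders *z·i* (19 covariates:
serum chemistry, vitals, diabetes, BMI), the analysis proceeds in two stages:

**Stage 1 — risk scoring.** A multivariate Cox proportional-hazards model
per nutrient,

    h(t | x, z) = h0(t) · exp(β x + γᵀz),

fitted by Efron-corrected partial likelihood, reports the hazard ratio
exp(β) per scaled unit with its Wald 95% CI, and yields a per-patient
dietary evaluation score

    sᵢ = exp(ηᵢ − mean(η)),   ηᵢ = β xᵢ + γᵀzᵢ,

the exponentiated mean-centered linear predictor (geometric mean 1).

**Stage 2 — dose–response.** log *s* is regressed on a restricted cubic
spline basis of the intake (4 knots at the 5/35/65/95th percentiles,
Harrell's convention); nested F-tests give the overall P and the
nonlinearity P (spline vs. straight line). The fitted log-HR curve,
centered to mean zero over the group's intake distribution, defines the
protective set {x : HR(x) < 1}, reported as points **A, B, C** — the
intervals [A, B] and optionally [C, ∞).

Before both stages, exposures are **two-level time averages**: records are
averaged within 6-month windows anchored at each patient's entry, empty
windows are dropped, and window means are averaged again. Labs are imputed
by last observation carried forward; dietary records are never imputed.
Patients are subtyped into low/medium/high groups at the tertiles of
baseline serum albumin, the standard marker of nutritional adequacy in PD.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
656-patient cohort whose truth contains two U-shaped nutrients (protein
centered at 52.5 g/d, dietary fiber at 10.2 g/d), a linearly protective one
(fat) and a linearly harmful one (sodium):

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_stratify.py
python analysis/04_stage1.py
python analysis/05_stage2.py
python analysis/06_check_tables.py
```

Output of the run at seed 42 (abridged):

```
  patients: 656, visits: 11640, diet records: 9271
642 profiles written (14 patients excluded)
albumin tertile cutpoints: 35.2 / 39.3 g/l; groups low=214 medium=214 high=214
log-rank across the three groups: P = 1.18e-18
whole-cohort column: 1/26 nutrients associated with mortality (P < 0.05)
recovered vs ground-truth protective ranges (whole cohort):
   Protein: estimated [37.17, 65.86), truth (36.78, 68.26), P-NL = 9.03e-15
        Df: estimated [6.69, 13.64), truth (6.48, 13.88), P-NL = 9.96e-19
       Fat: estimated [59.25, -), truth (61.30, inf), P-NL = 5.38e-01
        Na: estimated [1163.67, 2797.57), truth (0.00, 2602.73), P-NL = 1.05e-02
```

Read this as the package's core claim in miniature: the linear stage-1 scan
sees almost nothing (only the genuinely linear fat effect reaches P < 0.05),
while stage 2 recovers both U-shaped protective ranges to within a fraction
of an intake SD and correctly declares the fat effect linear (P-NL = 0.54).

The same steps are available as a CLI (`dietrisk simulate|preprocess|
stratify|stage1|stage2|run|check-tables`).

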
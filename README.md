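# genmr

Generation-standardized Mendelian randomization of **age at menarche (AAM)**
on **young-adult BMI**, with synthetic cohorts of known causal structure.

## The problem

Mean age at menarche fell by about four years across twentieth-century
Korean birth cohorts while schooling expanded from a small minority to near
universality. A crude regression of young-adult BMI on AAM therefore
confounds any causal effect with education and with the secular co-movement
of both traits across generations. `genmr` is for epidemiologists and
biostatisticians who want that analysis — and every estimator inside it —
as tested, reusable code:

* **generation standardization** — a data-driven segmentation of birth years
  into cohorts with homogeneous early-menarche (AAM < 14) prevalence, and
  gsAAM, the within-birth-year z-score
  `gsAAM = (AAM − μ_y) / σ_y` against a reference population, plus a
  cohort-relative "highly educated" indicator;
* **instrument construction** — genotype QC (call rate, MAF, Hardy-Weinberg),
  in-sample replication with directional consistency, and an unweighted
  genetic risk score (GRS) counting menarche-advancing alleles, with
  F / R² strength diagnostics and confounder-balance checks;
* **the MR estimator suite**, implemented from its defining formulas:
  observational OLS under four covariate models, two-stage least squares
  (β̂ from BMI on the GRS-predicted exposure; SE by 1000-replication pairs
  bootstrap), per-SNP Wald ratios β_Y/β_X, the inverse-variance-weighted
  mean β̂_IVW = Σ(β_X β_Y/se_Y²)/Σ(β_X²/se_Y²), the weighted median, MR-Egger
  regression (slope + pleiotropy intercept), MR-PRESSO
  (global/outlier/distortion tests), Cochran's Q and leave-one-out scans;
* **a synthetic-cohort generator** with configurable causal effect,
  pleiotropy, education confounding and secular trends, so every stage is
  testable against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on two simulated
cohorts (n = 10,000 each): one with a true causal effect of
β = −0.5 kg/m² per year of AAM, and one **null** cohort where any
observational association is pure confounding.

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_standardize.py
python analysis/03_build_instruments.py
python analysis/04_run_mr_models.py
python analysis/05_make_report_tables.py
```

`03` prints the instrument diagnostics:

```
effect: 14 candidates -> 14 pass QC -> 10 replicated (p<0.05, direction-consistent)
  first stage: AAM changes -0.104 y per GRS unit, F=96.0, R2=0.0095 (strong instrument)
```

— each extra risk allele advances menarche by ~0.1 years and the partial
F of 96 is far above the weak-instrument rule of thumb of 10. `04` prints
the headline contrast (observational vs 2SLS, per model):

```
== effect cohort (true beta: -0.5) ==
crude observational: -0.322 [-0.349, -0.295] p=2.8e-119
model1: obs -0.497 [-0.531,-0.463] | 2SLS -0.645 [-0.959,-0.338]
adjusted MR (AAM): IVW -0.627, WM -0.683, Egger slope -0.299 (intercept -0.035), Q=7.7 (p=0.56)

== null cohort (true beta: 0.0) ==
crude observational: +0.178 [+0.151, +0.205] p=2.8e-38
model1: obs +0.003 [-0.031,+0.037] | 2SLS -0.145 [-0.459,+0.162]
adjusted MR (AAM): IVW -0.127, WM -0.183, Egger slope +0.201 (intercept -0.035), Q=8.3 (p=0.51)
```

Read: in the null cohort the crude slope (+0.18, p ≈ 10⁻³⁸) is entirely an
artifact of secular trends and education, while every MR estimate covers
zero; in the effect cohort the estimators recover β ≈ −0.5. Models 3–4 use
gsAAM, so their coefficients are per SD of AAM (≈ 1.6 years) and larger in
magnitude. The Egger intercepts near 0 correctly report no directional
pleiotropy, and the homogeneous Q statistics show no heterogeneity to
prune. Plot-ready forest and leave-one-out tables land in `results/tables/`.

The same pipeline is scriptable stage by stage via the `genmr` CLI
(`simulate`, `standardize`, `instrument`, `analyze`, `report`); see
`genmr --help`.

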
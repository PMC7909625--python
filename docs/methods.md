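# Methods

## The problem

Age at menarche (AAM) in South Korea fell from about 16.5 years for women
born in the late 1920s to about 12.4 years for those born around 2000, while
educational attainment expanded just as dramatically. Any crude association
between AAM and young-adult BMI therefore mixes three things: a possible
causal effect of menarcheal timing on adiposity, confounding by education
(which tracks both), and the purely secular co-movement of AAM and BMI
across birth cohorts. `genmr` implements the analysis strategy for this
problem — generation standardization of the exposure, a genetic-risk-score
(GRS) instrument, and a full Mendelian-randomization (MR) estimator suite —
and validates every stage on synthetic cohorts whose causal structure is
known exactly.

## Generative model

Per individual *i* with birth year *y<sub>i</sub>* and dosage
*G<sub>ij</sub>* ∈ {0,1,2} at SNP *j* (Hardy-Weinberg proportions,
independent SNPs):

    educ_i ~ Categorical(p(y_i))                    (later cohorts more educated)
    AAM_i  = trend(y_i) + Σ_j e_j G_ij + γ_a educ_i + N(0, σ_a)
    BMI_i  = β AAM_i + Σ_j α_j G_ij + γ_b educ_i + shift(y_i) + N(0, σ_b)

β is the causal effect of interest; α<sub>j</sub> are direct (pleiotropic)
SNP→BMI effects, zero by default, i.e. valid instruments.

Defaults (`SimulationConfig`), chosen to match the observed Korean-cohort
scale:

| parameter | default | unit / rationale |
|---|---|---|
| `n_individuals` | 10,000 | matches the instrument-diagnostic sample |
| `birth_year_range` | 1927–2003 | observed span |
| `n_snps` | 14 | the replicated menarche panel size |
| `effect_allele_freqs` | 0.15–0.45 (linear) | common-variant range |
| `snp_effects_on_aam` | −0.12 … −0.04 y/allele | mean −0.08, the per-GRS-unit AAM shift observed; spread gives MR-Egger leverage |
| `beta_causal` | 0 | the null the study reports; set explicitly in scenarios |
| `educ_effect_on_aam` / `_bmi` | −0.10 y / −0.20 kg/m² per level | illustrative confounding (real within-cohort values are not published) |
| `secular_trend` | 16.5 → 12.4 y linear | observed endpoints |
| `cohort_bmi_shift` | 21.8 → 20.5 kg/m² linear | observed generational BMI baseline |
| `aam_noise_sd` / `bmi_noise_sd` | 1.6 y / 2.8 kg/m² | observed within-cohort SDs |
| `genotype_missing_rate` | 0 | missingness only when explicitly configured |

The reference population (the standardization substrate) draws AAM around
the secular trend only — it characterizes the *marginal* per-year AAM
distribution, so its per-year mean equals the trend. Because the study
cohort additionally carries genetic and education AAM shifts, gsAAM computed
against this reference has a common nonzero offset; this is irrelevant to
every estimator (all are slopes).

What the generator does **not** emulate: linkage disequilibrium between
instruments, genotyping-batch or imputation artifacts, family/twin
structure, non-Gaussian phenotype noise, informative missingness, and
selection into the cohort. Passing tests therefore certify the estimators
and pipeline logic under the linear-Gaussian causal model, not robustness
to those real-data features.

## Birth-cohort segmentation

Cohorts are grown greedily left to right over the reference years. "Early
menarche" is AAM < 14 (strict; the published anchor proportion 5.08% fixes
the cutoff but not the inequality — strict is used). Two stopping rules
close the open cohort before year K+1, whichever fires first:

* **band exit** — pooling year K+1 into the open cohort would move its
  cumulative early-menarche proportion outside [5%, 6%]. The band is
  evaluated on the open cohort's pooled proportion (a running constraint),
  and only governs cohorts whose opening year already lies inside the band:
  modern years with 40% early menarche are segmented by the jump rule alone
  (the published fourth cohort plainly violates the band, so the band cannot
  be globally binding). A `band_mode="marginal"` switch applies the band to
  each successive year's own proportion instead; the pooled reading is the
  default.
* **jump** — the per-year proportion changes by more than 2 percentage
  points between K and K+1.

The final cohort absorbs trailing years. On toy references (≤ 15 years) the
greedy output is verified to be the *unique* partition satisfying the rules
by exhaustive enumeration. Reference years with fewer than 30 observations
are neighbour-pooled before use (the source is silent on sparse years).

## Generation standardization

gsAAM is the within-birth-year z-score,
(AAM − μ<sub>y</sub>) / σ<sub>y</sub>, with μ, σ from the reference.
The "highly educated" indicator is cohort-relative: elementary school or
higher in the oldest cohort, high school or higher in the second,
university/college in later cohorts (5-level codebook: under elementary,
elementary, middle school, high school, university/college or higher).

## Instruments

QC retains a SNP iff call rate > 0.95, MAF > 0.01 and HWE χ² p > 10⁻⁶
(samples with call rate ≤ 0.9 are dropped first). HWE uses the 1-df χ²
goodness-of-fit (array-QC convention); an exact conditional test is
available as an option. Candidates must then replicate in-sample: unadjusted
AAM-on-dosage regression with p < 0.05 and the published direction of
effect; an explicit exclusion list handles externally documented pleiotropy.

The GRS is the **unweighted** count of menarche-advancing alleles (dosage
flipped to 2−G for SNPs whose effect allele delays menarche), so higher GRS
⇒ earlier expected menarche; coefficients are reported per 1-unit and per
quartile increase, matching the reporting convention. A weighted variant
would require published per-SNP weights the analysis does not use. Missing
dosages are mean-imputed per SNP for scoring only. Quartiles are rank-based
with ties to the lower quartile. Instrument strength is the partial F (and
partial R²) of the GRS over the covariate set; with no covariates this
reduces to F = (n−2)R²/(1−R²).

## Estimators

* **Observational OLS** under four covariate models: (1) AAM + birth-year
  dummies + 5-level education; (2) AAM + cohort dummies + highly-educated;
  (3) gsAAM + 5-level education; (4) gsAAM + highly-educated. Year, cohort
  and education enter as dummy indicators; analytic t CIs; complete-case
  within each model.
* **2SLS**: stage 1 regresses the exposure on the instrument (quartile-coded
  GRS by default, continuous optional) plus covariates; stage 2 regresses
  BMI on the fitted exposure plus covariates. SE/CI by a seeded
  nonparametric pairs bootstrap, 1000 replications, percentile interval.
  The bootstrap is computed via multinomial resampling weights applied to
  cross-product moment matrices — algebraically identical to refitting on
  resampled rows, verified against a literal resample to 1e−8.
* **Per-SNP summaries**: covariate-adjusted OLS of exposure and outcome on
  each oriented dosage via Frisch–Waugh residualization (identical to the
  full fit, tested against statsmodels). Adjustment defaults to the
  generation-adjusted covariate sets (model 2 for AAM, model 4 for gsAAM);
  unadjusted summaries are available.
* **Wald ratio** β<sub>Y</sub>/β<sub>X</sub> with first-order delta SE
  se<sub>Y</sub>/|β<sub>X</sub>|.
* **IVW**: fixed-effect, β = Σ(β<sub>X</sub>β<sub>Y</sub>/se<sub>Y</sub>²) /
  Σ(β<sub>X</sub>²/se<sub>Y</sub>²), SE = (Σβ<sub>X</sub>²/se<sub>Y</sub>²)^−½
  — the precision-weighted mean of the Wald ratios (identity tested).
* **Weighted median**: ratios ordered, estimate at the 0.5 crossing of the
  standardized cumulative inverse-variance weights, linear interpolation
  between bracketing ratios. SE by parametric bootstrap (summaries redrawn
  from N(β, se), 1000 draws, seeded); this SE is known to be somewhat
  conservative.
* **MR-Egger**: summaries oriented so all β<sub>X</sub> ≥ 0 (β<sub>Y</sub>
  flipped jointly — required for the intercept to mean average directional
  pleiotropy per exposure-increasing allele), then weighted regression of
  β<sub>Y</sub> on β<sub>X</sub> with weights 1/se<sub>Y</sub>², t CIs on
  K−2 df.
* **Cochran's Q** = Σ w<sub>j</sub>(ratio<sub>j</sub> − β<sub>ref</sub>)²,
  w<sub>j</sub> = β<sub>Xj</sub>²/se<sub>Yj</sub>², χ² with K−1 df.
* **MR-PRESSO**: observed statistic is the weighted RSS of each SNP's
  outcome beta about its leave-one-out IVW prediction; the null distribution
  comes from 1000 parametric simulations of β<sub>Y</sub> given
  β<sub>X</sub> and the SEs. Per-SNP outlier p-values are
  Bonferroni-adjusted at 0.05; outliers are removed and IVW re-estimated;
  the distortion p compares the observed before/after shift with the same
  shift in the null simulations.
* **Leave-one-out**: IVW and Q re-estimated with each SNP excluded in turn;
  the heterogeneity driver is the exclusion that collapses Q.

One master seed drives simulation, bootstrap, weighted-median and PRESSO
draws (spawned sub-seeds, all below 2³¹).

## Validation scenarios and Monte-Carlo sizes

Two scenario families are used deliberately:

* **Full study conditions** (secular trend + education confounding + cohort
  BMI baseline): null-calibration coverage (1,000 cohorts, n = 5,000;
  2SLS/WM bootstraps at 600 draws there) and the observational-vs-MR
  contrast. In this regime the *crude* observational slope is strongly
  biased while the four adjusted models are not — the generator contains no
  unmeasured confounder, so unlike in real data the named models fully block
  the configured paths; the qualitative contrast is therefore demonstrated
  against the crude fit.
* **Valid-instrument conditions** (confounding channels off; the secular
  trend stays, reaching BMI only through the causal path): parameter
  recovery (200 cohorts, n = 10,000), IVW–2SLS equivalence (mean signed gap
  over 10 cohorts, n = 50,000 — a single cohort's gap carries ≈ 0.025 of
  Monte-Carlo noise), weighted-median robustness (40 cohorts, n = 100,000,
  pleiotropy +0.1 kg/m² per allele on the six weakest instruments ≈ 43% of
  SNPs and ≈ 18% of IVW weight, below the 50% validity bound), and Egger
  intercept recovery (200 cohorts, n = 10,000, constant α = 0.05 in the
  oriented frame). With confounding on and *unadjusted* summaries, the
  one-sample exposure/outcome errors share non-causal components and the
  Egger slope attenuates — a regime property, not an estimator defect; the
  estimators match statsmodels/IV2SLS oracles to 1e−8 either way.

Heterogeneity-test calibration (1,000 replicates, K = 14) and MR-PRESSO
detection/type-I (100 / 300 replicates) use parametric summary tables
directly.

## Numerical choices and degenerate inputs

Rank-deficient designs raise errors naming the aliased columns; a
zero-variance instrument or a first stage with zero fitted variance is
rejected; monomorphic SNPs yield HWE p = 1 by convention, are dropped from
summary tables with a warning, and make the Wald ratio undefined (error).
Quartiles require ≥ 4 distinct values. Weighted-median draws that hit
β<sub>X</sub> = 0 are nudged to the smallest positive float. CIs use
t quantiles where a residual df exists (OLS, Egger) and normal quantiles
for summary-data estimators; the 2SLS interval is the percentile bootstrap.

## Known limitations

MR-Egger is noisy and finite-sample biased when the spread of exposure
betas is small relative to their SEs (the realistic menarche-panel regime);
the weighted-median bootstrap SE over-covers slightly; MR-PRESSO simulates
outcome betas only (exposure betas treated as fixed); no LD-aware IVW, no
two-sample MR against external summary databases, no genotype imputation.
The printed four-cohort partition of the real reference data is not
reproducible here because that individual-level reference is not public;
the segmentation algorithm is instead validated exhaustively on synthetic
references.
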
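"""Estimator oracles: hand-computed examples, brute-force normal equations,
statsmodels cross-checks, and the algebraic identities tying the estimators
together."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genmr import (
    MODELS,
    ModelSpec,
    SimulationConfig,
    build_grs,
    cochran_q,
    fit_2sls,
    fit_observational,
    grs_quartiles,
    ivw,
    leave_one_out,
    mr_egger,
    mr_presso,
    simulate_cohort,
    snp_summary_stats,
    wald_ratio,
    weighted_median,
)
from genmr.mr import _tsls_from_moments, _weighted_moments
from genmr.simulate import CohortData

from conftest import make_summaries

BARE = ModelSpec("bare", "aam", ())  # exposure only, no covariates


def cohort_from(pheno: pd.DataFrame) -> CohortData:
    geno = pd.DataFrame({"dummy": np.zeros(len(pheno))}, index=pheno.index)
    return CohortData(pheno.reset_index(drop=True), geno)


def summaries_from(bx, by, sy, sx=None):
    k = len(bx)
    return pd.DataFrame(
        {"snp": [f"rs{j}" for j in range(k)], "beta_exposure": bx,
         "se_exposure": sx if sx is not None else np.full(k, 0.01),
         "beta_outcome": by, "se_outcome": sy}
    )


# ---------------------------------------------------------------------------
# observational OLS
# ---------------------------------------------------------------------------

def test_observational_exact_line():
    x = np.linspace(10, 18, 40)
    pheno = pd.DataFrame({"aam": x, "bmi_young_adult": 2 * x})
    est = fit_observational(cohort_from(pheno), BARE)
    assert est.beta == pytest.approx(2.0, abs=1e-10)
    assert est.r2 == pytest.approx(1.0, abs=1e-10)


def test_observational_matches_statsmodels_with_covariates():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    n = 250
    pheno = pd.DataFrame(
        {"aam": rng.normal(14, 1.5, n), "bmi_young_adult": rng.normal(21, 2, n),
         "education": rng.integers(1, 6, n), "birth_year": rng.integers(1950, 1955, n)}
    )
    spec = MODELS["model1"]
    est = fit_observational(cohort_from(pheno), spec)
    X = sm.add_constant(
        pd.concat([pheno[["aam"]], spec.covariates(pheno)], axis=1).astype(float)
    )
    ref = sm.OLS(pheno["bmi_young_adult"], X).fit()
    assert est.beta == pytest.approx(ref.params["aam"], abs=1e-8)
    assert est.se == pytest.approx(ref.bse["aam"], abs=1e-8)
    assert est.r2 == pytest.approx(ref.rsquared, abs=1e-8)
    lo, hi = ref.conf_int().loc["aam"]
    assert est.ci_low == pytest.approx(lo, abs=1e-8)
    assert est.ci_high == pytest.approx(hi, abs=1e-8)


def test_observational_collinear_design_names_columns():
    pheno = pd.DataFrame(
        {"aam": [14, 15, 16, 14.5], "bmi_young_adult": [20, 21, 22, 20.5],
         "highly_educated": [1, 1, 1, 1]}  # constant: aliased with intercept
    )
    with pytest.raises(np.linalg.LinAlgError, match="highly_educated"):
        fit_observational(cohort_from(pheno), MODELS["model4"].__class__(
            "model4", "aam", ("highly_educated",)))


def test_observational_null_exposure_centered_on_zero():
    rng = np.random.default_rng(3)
    betas = []
    for _ in range(50):
        pheno = pd.DataFrame({"aam": rng.normal(size=400),
                              "bmi_young_adult": rng.normal(size=400)})
        betas.append(fit_observational(cohort_from(pheno), BARE).beta)
    assert np.mean(betas) == pytest.approx(0.0, abs=0.03)


def test_observational_confounding_biases_unadjusted_estimate():
    """Education driving both AAM and BMI biases the crude slope by gamma*delta."""
    cfg = SimulationConfig(
        n_individuals=40_000, beta_causal=0.0, educ_effect_on_aam=-0.5,
        educ_effect_on_bmi=-1.0, secular_trend=15.0, cohort_bmi_shift=0.0,
        snp_effects_on_aam=np.zeros(14), seed=21,
    )
    data, _ = simulate_cohort(cfg)
    est = fit_observational(data, BARE)
    e = data.phenotypes["education"].to_numpy(float)
    a = data.phenotypes["aam"].to_numpy(float)
    # omitted-variable algebra: bias = delta * cov(educ, aam)/var(aam) * ... =
    # (gamma*delta*var(educ)) / var(aam) with gamma, delta the two paths
    expected = (-0.5 * -1.0 * np.var(e)) / np.var(a)
    assert est.beta == pytest.approx(expected, abs=3 * est.se)
    assert est.p < 0.01  # bias is resolvable at this n


# ---------------------------------------------------------------------------
# 2SLS
# ---------------------------------------------------------------------------

def test_2sls_equals_wald_ratio_on_hand_dataset():
    z = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    x = np.array([13.0, 14.0, 15.0, 12.0, 13.5, 12.5])
    y = np.array([22.0, 21.0, 23.0, 24.0, 25.0, 23.5])
    wald = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
    pheno = pd.DataFrame({"aam": x, "bmi_young_adult": y})
    est = fit_2sls(cohort_from(pheno), BARE, z, n_boot=0)
    assert est.beta == pytest.approx(wald, abs=1e-10)


def test_2sls_noiseless_identity():
    z = np.arange(20, dtype=float)
    pheno = pd.DataFrame({"aam": z, "bmi_young_adult": 2 * z})
    est = fit_2sls(cohort_from(pheno), BARE, z, n_boot=0)
    assert est.beta == pytest.approx(2.0, abs=1e-10)


def test_2sls_matches_statsmodels_iv2sls_with_covariates():
    from statsmodels.sandbox.regression.gmm import IV2SLS

    rng = np.random.default_rng(8)
    n = 300
    pheno = pd.DataFrame(
        {"aam": rng.normal(14, 1.5, n), "bmi_young_adult": rng.normal(21, 2, n),
         "highly_educated": rng.integers(0, 2, n).astype(float)}
    )
    z = rng.normal(size=n) + 0.5 * pheno["aam"].to_numpy()
    spec = ModelSpec("m", "aam", ("highly_educated",))
    est = fit_2sls(cohort_from(pheno), spec, z, n_boot=0)
    exog = np.column_stack([np.ones(n), pheno["aam"], pheno["highly_educated"]])
    instr = np.column_stack([np.ones(n), z, pheno["highly_educated"]])
    ref = IV2SLS(pheno["bmi_young_adult"].to_numpy(), exog, instrument=instr).fit()
    assert est.beta == pytest.approx(ref.params[1], abs=1e-8)


def test_2sls_moment_bootstrap_equals_explicit_resample():
    """The multinomial-weight moment path reproduces a literal resampled 2SLS."""
    rng = np.random.default_rng(9)
    n = 60
    z = rng.normal(size=n)
    c = rng.normal(size=n)
    x = 0.8 * z + 0.3 * c + rng.normal(size=n)
    y = -0.5 * x + 0.4 * c + rng.normal(size=n)
    X1 = np.column_stack([np.ones(n), z, c])
    C = np.column_stack([X1, x, y])
    idx = rng.integers(0, n, size=n)
    W = np.bincount(idx, minlength=n)[None, :]
    S = _weighted_moments(C, W)
    beta_m, _ = _tsls_from_moments(S, 3, batched=True)
    # literal two-stage on the resampled rows
    Xr, xr, yr = X1[idx], x[idx], y[idx]
    b1 = np.linalg.lstsq(Xr, xr, rcond=None)[0]
    fitted = Xr @ b1
    X2 = np.column_stack([np.ones(n), fitted, Xr[:, 2]])
    b2 = np.linalg.lstsq(X2, yr, rcond=None)[0]
    assert beta_m[0] == pytest.approx(b2[1], abs=1e-8)


def test_2sls_bootstrap_ci_brackets_estimate_and_is_seeded():
    rng = np.random.default_rng(10)
    n = 500
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = -0.5 * x + rng.normal(size=n)
    pheno = pd.DataFrame({"aam": x, "bmi_young_adult": y})
    est1 = fit_2sls(cohort_from(pheno), BARE, z, n_boot=400, seed=1)
    est2 = fit_2sls(cohort_from(pheno), BARE, z, n_boot=400, seed=1)
    assert est1 == est2
    assert est1.ci_low < est1.beta < est1.ci_high
    assert est1.se > 0
    assert est1.beta == pytest.approx(-0.5, abs=4 * est1.se)


def test_2sls_degenerate_instrument_rejected():
    pheno = pd.DataFrame({"aam": [14.0, 15, 16, 14], "bmi_young_adult": [20.0, 21, 22, 20]})
    with pytest.raises(ValueError, match="vary"):
        fit_2sls(cohort_from(pheno), BARE, np.ones(4), n_boot=0)


# ---------------------------------------------------------------------------
# per-SNP summaries
# ---------------------------------------------------------------------------

def test_snp_summaries_recover_generative_algebra():
    """beta_outcome ~= beta_exposure * beta_causal for valid instruments."""
    cfg = SimulationConfig(n_individuals=30_000, beta_causal=-0.5, seed=22)
    data, panel = simulate_cohort(cfg)
    summ = snp_summary_stats(data, panel, spec=BARE, adjusted=False)
    assert len(summ) == 14
    pred = summ["beta_exposure"] * -0.5
    resid = summ["beta_outcome"] - pred
    assert np.all(np.abs(resid) < 4 * summ["se_outcome"])
    # oriented to the menarche-advancing allele: exposure betas negative
    assert (summ["beta_exposure"] < 0).all()


def test_snp_summaries_match_per_snp_statsmodels_fit():
    import statsmodels.api as sm

    cfg = SimulationConfig(
        n_individuals=800, birth_year_range=(1950, 1959), n_snps=3,
        effect_allele_freqs=[0.2, 0.3, 0.4],
        snp_effects_on_aam=[-0.2, -0.15, -0.1], beta_causal=-0.5, seed=23,
    )
    data, panel = simulate_cohort(cfg)
    data.phenotypes["highly_educated"] = (data.phenotypes["education"] >= 4).astype(int)
    data.phenotypes["cohort"] = np.where(data.phenotypes["birth_year"] < 1955, "a", "b")
    spec = MODELS["model2"]
    summ = snp_summary_stats(data, panel, spec=spec)
    cov = spec.covariates(data.phenotypes).astype(float)
    for _, row in summ.iterrows():
        g = data.genotypes[row["snp"]].to_numpy(float)
        X = sm.add_constant(pd.concat(
            [pd.Series(g, name="g", index=data.phenotypes.index), cov], axis=1))
        fit_x = sm.OLS(data.phenotypes["aam"], X).fit()
        fit_y = sm.OLS(data.phenotypes["bmi_young_adult"], X).fit()
        assert row["beta_exposure"] == pytest.approx(fit_x.params["g"], abs=1e-8)
        assert row["se_exposure"] == pytest.approx(fit_x.bse["g"], abs=1e-8)
        assert row["beta_outcome"] == pytest.approx(fit_y.params["g"], abs=1e-8)
        assert row["se_outcome"] == pytest.approx(fit_y.bse["g"], abs=1e-8)


def test_snp_summaries_drop_monomorphic_with_warning():
    cfg = SimulationConfig(
        n_individuals=100, birth_year_range=(1950, 1951), n_snps=2,
        effect_allele_freqs=[0.3, 0.4], snp_effects_on_aam=[-0.2, -0.2], seed=24,
    )
    data, panel = simulate_cohort(cfg)
    data.genotypes.iloc[:, 0] = 1.0  # constant dosage
    with pytest.warns(UserWarning, match="monomorphic"):
        summ = snp_summary_stats(data, panel, spec=BARE, adjusted=False)
    assert len(summ) == 1


# ---------------------------------------------------------------------------
# Wald ratio / IVW / Q
# ---------------------------------------------------------------------------

def test_wald_ratio_arithmetic_and_invariance():
    s = {"snp": "rs1", "beta_exposure": 0.5, "se_exposure": 0.05,
         "beta_outcome": 0.1, "se_outcome": 0.08}
    est = wald_ratio(s)
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.08 / 0.5)
    flipped = dict(s, beta_exposure=-0.5, beta_outcome=-0.1)
    est2 = wald_ratio(flipped)
    assert est2.beta == pytest.approx(est.beta)
    assert est2.se == pytest.approx(est.se)
    null = wald_ratio(dict(s, beta_outcome=0.0))
    assert null.beta == 0.0 and null.se == pytest.approx(0.16)
    with pytest.raises(ZeroDivisionError):
        wald_ratio(dict(s, beta_exposure=0.0))


def test_ivw_hand_computation():
    summ = summaries_from([0.5, 0.25], [0.1, 0.05], [0.1, 0.1])
    est, het = ivw(summ)
    assert est.beta == pytest.approx(0.2, abs=1e-12)
    assert est.se == pytest.approx(np.sqrt(1 / 31.25), abs=1e-12)
    assert est.se == pytest.approx(0.1789, abs=1e-4)
    assert het.Q == pytest.approx(0.0, abs=1e-20)


def test_ivw_equals_precision_weighted_wald_ratios():
    summ = make_summaries(np.random.default_rng(1))
    est, _ = ivw(summ)
    ratios = np.array([wald_ratio(row).beta for _, row in summ.iterrows()])
    ses = np.array([wald_ratio(row).se for _, row in summ.iterrows()])
    w = 1 / ses**2
    assert est.beta == pytest.approx(float((w * ratios).sum() / w.sum()), abs=1e-12)
    assert est.se == pytest.approx(float(np.sqrt(1 / w.sum())), abs=1e-12)


def test_ivw_identical_ratios_and_minimum_size():
    summ = summaries_from([0.5, 0.25], [0.1, 0.05], [0.1, 0.2])
    est, _ = ivw(summ)
    assert est.beta == pytest.approx(0.2, abs=1e-12)  # any weights
    with pytest.raises(ValueError, match="at least 2"):
        ivw(summ.iloc[:1])


def test_cochran_q_hand_computation():
    summ = summaries_from([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
    est, het = ivw(summ)
    assert est.beta == pytest.approx(0.2, abs=1e-12)
    assert het.Q == pytest.approx(2.0, abs=1e-10)
    assert het.df == 1
    assert het.p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-10)
    same = cochran_q(summ, 0.2)
    assert same.Q == pytest.approx(2.0, abs=1e-10)
    hom = cochran_q(summaries_from([0.5, 0.25], [0.1, 0.05], [0.1, 0.1]), 0.2)
    assert hom.Q == pytest.approx(0.0, abs=1e-20) and hom.p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_interpolation_rule():
    # equal weights, ratios (0.1, 0.2, 0.3): cumulative weight hits 0.5 at 0.2
    summ = summaries_from([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
    est = weighted_median(summ, n_boot=0)
    assert est.beta == pytest.approx(0.2, abs=1e-12)
    # all ratios equal c -> c
    summ = summaries_from([0.5, 1.0, 2.0], [0.15, 0.3, 0.6], [0.1, 0.1, 0.1])
    est = weighted_median(summ, n_boot=0)
    assert est.beta == pytest.approx(0.3, abs=1e-12)
    with pytest.raises(ValueError, match="at least 3"):
        weighted_median(summ.iloc[:2])


def test_weighted_median_seeded_and_se_positive():
    summ = make_summaries(np.random.default_rng(4))
    a = weighted_median(summ, n_boot=300, seed=5)
    b = weighted_median(summ, n_boot=300, seed=5)
    assert a == b and a.se > 0 and a.ci_low < a.beta < a.ci_high


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_collinear_through_origin():
    summ = summaries_from([0.2, 0.5, 0.8], [0.1, 0.25, 0.4], [0.1, 0.1, 0.1])
    egger, het = mr_egger(summ)
    assert egger.slope.beta == pytest.approx(0.5, abs=1e-10)
    assert egger.intercept.beta == pytest.approx(0.0, abs=1e-10)
    assert het.Q == pytest.approx(0.0, abs=1e-16)


def test_egger_two_point_line_algebra():
    # line through (0.25, 0.05), (0.5, 0.15): slope 0.4, intercept -0.05
    summ = summaries_from([0.25, 0.5, 0.75], [0.05, 0.15, 0.25], [0.1, 0.1, 0.1])
    egger, _ = mr_egger(summ)
    assert egger.slope.beta == pytest.approx(0.4, abs=1e-10)
    assert egger.intercept.beta == pytest.approx(-0.05, abs=1e-10)


def test_egger_matches_statsmodels_wls():
    import statsmodels.api as sm

    summ = make_summaries(np.random.default_rng(6))
    egger, _ = mr_egger(summ)
    bx = -summ["beta_exposure"]  # orientation flip: betas made non-negative
    by = -summ["beta_outcome"]
    X = sm.add_constant(bx.to_numpy())
    ref = sm.WLS(by.to_numpy(), X, weights=1 / summ["se_outcome"] ** 2).fit()
    assert egger.intercept.beta == pytest.approx(ref.params[0], abs=1e-10)
    assert egger.slope.beta == pytest.approx(ref.params[1], abs=1e-10)
    assert egger.slope.se == pytest.approx(ref.bse[1], abs=1e-10)
    lo, hi = ref.conf_int()[1]
    assert egger.slope.ci_low == pytest.approx(lo, abs=1e-8)
    assert egger.slope.ci_high == pytest.approx(hi, abs=1e-8)


def test_egger_orientation_invariance_and_errors():
    summ = make_summaries(np.random.default_rng(7))
    flipped = summ.copy()
    flipped["beta_exposure"] *= -1
    flipped["beta_outcome"] *= -1
    a, _ = mr_egger(summ)
    b, _ = mr_egger(flipped)
    assert a.slope.beta == pytest.approx(b.slope.beta, abs=1e-12)
    assert a.intercept.beta == pytest.approx(b.intercept.beta, abs=1e-12)
    degenerate = summaries_from([0.3, 0.3, 0.3], [0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
    with pytest.raises(ValueError, match="spread"):
        mr_egger(degenerate)


# ---------------------------------------------------------------------------
# MR-PRESSO and leave-one-out
# ---------------------------------------------------------------------------

def test_presso_homogeneous_input_no_outliers():
    summ = summaries_from([0.5, 0.25, 0.4, 0.8], [0.1, 0.05, 0.08, 0.16],
                          [0.1, 0.1, 0.1, 0.1])
    res = mr_presso(summ, n_sim=500, seed=1)
    assert res.outliers == []
    assert res.global_rss_observed == pytest.approx(0.0, abs=1e-16)
    assert res.global_p > 0.5
    assert np.isnan(res.distortion_p)
    with pytest.raises(ValueError, match="at least 4"):
        mr_presso(summ.iloc[:3])


def test_presso_flags_injected_outlier_and_corrects():
    rng = np.random.default_rng(11)
    summ = make_summaries(rng, outlier=3)
    res = mr_presso(summ, n_sim=1000, seed=2)
    assert "rs3" in res.outliers
    assert res.estimate_after is not None
    assert abs(res.estimate_after.beta - -0.5) < abs(res.estimate_before.beta - -0.5)
    assert res.global_p < 0.05
    assert res.distortion_p <= 1.0


def test_leave_one_out_bookkeeping_and_heterogeneity():
    # homogeneous: every row equals the full-sample estimate
    summ = summaries_from([0.5, 0.25, 0.4], [0.1, 0.05, 0.08], [0.1, 0.1, 0.1])
    full, _ = ivw(summ)
    tab = leave_one_out(summ)
    assert len(tab) == 3
    assert np.allclose(tab["beta"], full.beta, atol=1e-12)
    # one aberrant SNP: its exclusion row shows the smallest Q
    rng = np.random.default_rng(12)
    summ = make_summaries(rng, sy=0.02, outlier=5)
    tab = leave_one_out(summ)
    assert tab.loc[tab["Q"].idxmin(), "excluded_snp"] == "rs5"
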
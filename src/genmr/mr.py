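"""Mendelian-randomization estimator suite.

Individual-level estimators
---------------------------
* :func:`fit_observational` — conventional OLS of young-adult BMI on the
  exposure (AAM in years, or generation-standardized AAM) under one of four
  covariate specifications.
* :func:`fit_2sls` — two-stage least squares with the genetic risk score
  (quartile-coded or continuous) as the instrument; standard errors by a
  seeded nonparametric pairs bootstrap (percentile intervals).

Summary-data estimators, built on per-SNP association pairs
(beta_exposure, beta_outcome) with standard errors
-----------------------------------------------------------
* Wald ratio, inverse-variance-weighted (IVW) mean, weighted median,
  MR-Egger regression (slope + pleiotropy intercept), MR-PRESSO
  (global / outlier / distortion tests) and Cochran's Q, plus a
  leave-one-out IVW scan.

All estimators are implemented directly from their defining formulas; unit
tests check them against brute-force normal-equations solutions and
hand-computed examples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import add_intercept, check_full_rank, ols, t_ci_p
from .simulate import CohortData

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "EggerResult",
    "PressoResult",
    "ModelSpec",
    "MODELS",
    "fit_observational",
    "fit_2sls",
    "snp_summary_stats",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "mr_egger",
    "mr_presso",
    "cochran_q",
    "leave_one_out",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class MREstimate:
    """A causal-effect estimate: method, beta, SE, 95% CI and p-value."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int | None = None
    r2: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return d


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic across per-SNP Wald ratios."""

    Q: float
    df: int
    p: float


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: MREstimate


@dataclass
class PressoResult:
    global_rss_observed: float
    global_p: float
    outlier_p: pd.Series
    outliers: list[str]
    distortion_p: float
    estimate_before: MREstimate
    estimate_after: MREstimate | None


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One of the four covariate-adjustment specifications.

    model1: AAM (years)  + birth-year dummies + 5-level education dummies
    model2: AAM (years)  + birth-cohort dummies + highly-educated indicator
    model3: gsAAM        + 5-level education dummies
    model4: gsAAM        + highly-educated indicator
    """

    name: str
    exposure: str
    covariate_kinds: tuple[str, ...]

    def covariates(self, phenotypes: pd.DataFrame) -> pd.DataFrame:
        blocks = []
        for kind in self.covariate_kinds:
            if kind == "year_dummies":
                self._require(phenotypes, "birth_year")
                blocks.append(pd.get_dummies(
                    phenotypes["birth_year"].astype(int), prefix="by", drop_first=True, dtype=float))
            elif kind == "cohort_dummies":
                self._require(phenotypes, "cohort")
                blocks.append(pd.get_dummies(
                    phenotypes["cohort"].astype(str), prefix="cohort", drop_first=True, dtype=float))
            elif kind == "education_5level":
                self._require(phenotypes, "education")
                blocks.append(pd.get_dummies(
                    phenotypes["education"].astype(int), prefix="edu", drop_first=True, dtype=float))
            elif kind == "highly_educated":
                self._require(phenotypes, "highly_educated")
                blocks.append(phenotypes[["highly_educated"]].astype(float))
            else:  # pragma: no cover
                raise ValueError(f"unknown covariate kind {kind!r}")
        if not blocks:
            return pd.DataFrame(index=phenotypes.index)
        return pd.concat(blocks, axis=1)

    @staticmethod
    def _require(phenotypes: pd.DataFrame, column: str) -> None:
        if column not in phenotypes.columns:
            raise KeyError(f"phenotype table is missing required column {column!r}")

    @classmethod
    def get(cls, name: str) -> "ModelSpec":
        try:
            return MODELS[name]
        except KeyError:
            raise KeyError(f"unknown model {name!r}; expected one of {sorted(MODELS)}") from None


MODELS: dict[str, ModelSpec] = {
    "model1": ModelSpec("model1", "aam", ("year_dummies", "education_5level")),
    "model2": ModelSpec("model2", "aam", ("cohort_dummies", "highly_educated")),
    "model3": ModelSpec("model3", "gsaam", ("education_5level",)),
    "model4": ModelSpec("model4", "gsaam", ("highly_educated",)),
}


def _design(data: CohortData, spec: ModelSpec):
    """Complete-case (y, x, covariate array, covariate names)."""
    pheno = data.phenotypes
    spec._require(pheno, spec.exposure)
    spec._require(pheno, "bmi_young_adult")
    cov = spec.covariates(pheno)
    used = pd.concat([pheno[[spec.exposure, "bmi_young_adult"]], cov], axis=1)
    mask = ~used.isna().any(axis=1)
    y = pheno.loc[mask, "bmi_young_adult"].to_numpy(dtype=float)
    x = pheno.loc[mask, spec.exposure].to_numpy(dtype=float)
    C = cov.loc[mask].to_numpy(dtype=float) if cov.shape[1] else np.empty((mask.sum(), 0))
    return y, x, C, [str(c) for c in cov.columns], mask.to_numpy()


# ---------------------------------------------------------------------------
# observational OLS
# ---------------------------------------------------------------------------

def fit_observational(data: CohortData, spec: ModelSpec) -> MREstimate:
    """Conventional OLS of young-adult BMI on the exposure plus covariates."""
    y, x, C, names, _ = _design(data, spec)
    n = len(y)
    X = np.hstack([np.ones((n, 1)), x[:, None], C])
    check_full_rank(X, ["const", spec.exposure] + names)
    coef, se, rss, df = ols(y, X)
    lo, hi, p = t_ci_p(coef[1], se[1], df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return MREstimate("observational", float(coef[1]), float(se[1]), lo, hi, p, n=n, r2=r2)


# ---------------------------------------------------------------------------
# two-stage least squares with pairs bootstrap
# ---------------------------------------------------------------------------

def _weighted_moments(C: np.ndarray, W: np.ndarray, block: int = 256) -> np.ndarray:
    """S_b = C' diag(w_b) C for every bootstrap weight row, blocked.

    W holds multinomial resampling counts (one row per bootstrap replicate),
    so S_b equals the cross-product matrix of the resampled-with-replacement
    dataset — the pairs bootstrap without materializing any resample.
    """
    n, m = C.shape
    B = W.shape[0]
    iu, ju = np.triu_indices(m)
    S = np.empty((B, m, m))
    Wf = W.astype(float)
    for start in range(0, len(iu), block):
        sl = slice(start, min(start + block, len(iu)))
        K = C[:, iu[sl]] * C[:, ju[sl]]
        vals = Wf @ K
        S[:, iu[sl], ju[sl]] = vals
        S[:, ju[sl], iu[sl]] = vals
    return S


def _tsls_from_moments(S, p1, batched: bool):
    """2SLS exposure coefficient from cross-product moments.

    Column layout of the underlying data matrix: [1, instrument, covars...,
    exposure, outcome]; the first p1 columns are the stage-1 design. The
    stage-2 design [1, fitted, covars] lies in the span of the stage-1
    design, so both stages reduce to small linear solves on the moments.
    """
    A = S[..., :p1, :p1]
    cx = S[..., :p1, p1]
    cy = S[..., :p1, p1 + 1]
    beta1 = np.linalg.solve(A, cx[..., None])[..., 0]
    if batched:
        B = S.shape[0]
        T = np.zeros((B, p1, p1))
        T[:, 0, 0] = 1.0
        T[:, :, 1] = beta1
        idx = np.arange(2, p1)
        T[:, idx, idx] = 1.0
    else:
        T = np.zeros((p1, p1))
        T[0, 0] = 1.0
        T[:, 1] = beta1
        idx = np.arange(2, p1)
        T[idx, idx] = 1.0
    A2 = np.swapaxes(T, -1, -2) @ A @ T
    c2 = (np.swapaxes(T, -1, -2) @ cy[..., None])[..., 0]
    beta2 = np.linalg.solve(A2, c2[..., None])[..., 0]
    return beta2[..., 1], beta1


def fit_2sls(
    data: CohortData,
    spec: ModelSpec,
    instrument,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Two-stage least squares with the GRS (quartile or continuous) as IV.

    Stage 1 regresses the exposure on the instrument plus covariates; stage 2
    regresses the outcome on the stage-1 fitted exposure plus the same
    covariates. The stage-2 coefficient of the fitted exposure is the causal
    estimate. SE and 95% CI come from a seeded nonparametric pairs bootstrap
    (percentile interval, ``n_boot`` replications); with ``n_boot=0`` only
    the point estimate is returned.
    """
    y, x, C, names, mask = _design(data, spec)
    z = np.asarray(instrument, dtype=float)
    if len(z) == len(mask):
        z = z[mask]
    if len(z) != len(y):
        raise ValueError("instrument length does not match phenotype table")
    if np.nanstd(z) == 0:
        raise ValueError("instrument does not vary")
    n = len(y)
    X1 = np.hstack([np.ones((n, 1)), z[:, None], C])
    check_full_rank(X1, ["const", "instrument"] + names)
    Cmat = np.hstack([X1, x[:, None], y[:, None]])
    p1 = X1.shape[1]
    S = Cmat.T @ Cmat
    beta_point, beta1 = _tsls_from_moments(S, p1, batched=False)
    # weak/degenerate first stage: variance of the fitted exposure
    fitted_ss = beta1 @ S[:p1, :p1] @ beta1
    fitted_sum = S[0, :p1] @ beta1
    var_fitted = fitted_ss / n - (fitted_sum / n) ** 2
    if var_fitted <= 1e-12 * max(np.var(x), 1e-30):
        raise ValueError("degenerate first stage: fitted exposure has zero variance")
    beta_point = float(beta_point)
    if n_boot == 0:
        return MREstimate("2sls", beta_point, float("nan"), float("nan"), float("nan"),
                          float("nan"), n=n)
    rng = np.random.default_rng(seed)
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    S_boot = _weighted_moments(Cmat, W)
    with np.errstate(all="ignore"):
        betas, _ = _tsls_from_moments(S_boot, p1, batched=True)
    betas = betas[np.isfinite(betas)]
    if len(betas) < max(10, n_boot // 2):
        raise ValueError("bootstrap failed: too many degenerate resamples")
    se = float(np.std(betas, ddof=1))
    lo, hi = np.percentile(betas, [2.5, 97.5])
    p = 2 * stats.norm.sf(abs(beta_point) / se) if se > 0 else (0.0 if beta_point else 1.0)
    return MREstimate("2sls", beta_point, se, float(lo), float(hi), float(p), n=n)


# ---------------------------------------------------------------------------
# per-SNP summary statistics
# ---------------------------------------------------------------------------

def snp_summary_stats(
    data: CohortData,
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Per-SNP exposure and outcome associations with standard errors.

    For each panel SNP, OLS of the exposure on allele dosage and of the
    outcome on allele dosage, adjusted for the model's covariates (via
    Frisch-Waugh residualization, which reproduces the full-model
    coefficient and SE exactly). Dosages are oriented to the
    menarche-advancing allele so that beta_exposure is negative for a
    menarche-delaying exposure effect; missing dosages are mean-imputed.
    Monomorphic SNPs are dropped with a warning.
    """
    spec = spec or MODELS["model1"]
    exposure = spec.exposure
    pheno = data.phenotypes
    if exposure not in pheno.columns:
        raise KeyError(f"phenotype table is missing required column {exposure!r}")
    cov = spec.covariates(pheno) if adjusted else pd.DataFrame(index=pheno.index)
    n = len(pheno)
    X0 = add_intercept(cov.to_numpy(dtype=float) if cov.shape[1] else None, n)
    p0 = X0.shape[1]
    x = pheno[exposure].to_numpy(dtype=float)
    y = pheno["bmi_young_adult"].to_numpy(dtype=float)

    snps = [s for s in panel["snp"]]
    missing = [s for s in snps if s not in data.genotypes.columns]
    if missing:
        raise KeyError(f"panel SNP(s) absent from genotype matrix: {missing}")
    G = data.genotypes[snps].to_numpy(dtype=float).copy()
    direction = panel["published_direction"].to_numpy()
    # orient to the menarche-advancing allele (same convention as the GRS)
    G[:, direction > 0] = 2.0 - G[:, direction > 0]
    col_mean = np.nanmean(G, axis=0)
    nan = np.isnan(G)
    G[nan] = np.take(col_mean, np.where(nan)[1])

    mono = G.std(axis=0) == 0
    if mono.any():
        warnings.warn(
            f"dropping monomorphic SNP(s): {[snps[j] for j in np.where(mono)[0]]}",
            stacklevel=2,
        )
    keep = ~mono
    G = G[:, keep]
    kept_snps = [s for s, k in zip(snps, keep) if k]

    # Frisch-Waugh: residualize everything on the covariate block once.
    coefs, _, _, _ = np.linalg.lstsq(X0, np.column_stack([x, y, G]), rcond=None)
    R = np.column_stack([x, y, G]) - X0 @ coefs
    rx, ry, RG = R[:, 0], R[:, 1], R[:, 2:]
    gg = (RG * RG).sum(axis=0)
    bx = RG.T @ rx / gg
    by = RG.T @ ry / gg
    dof = n - p0 - 1
    rss_x = ((rx[:, None] - RG * bx) ** 2).sum(axis=0)
    rss_y = ((ry[:, None] - RG * by) ** 2).sum(axis=0)
    se_x = np.sqrt(rss_x / dof / gg)
    se_y = np.sqrt(rss_y / dof / gg)
    return pd.DataFrame(
        {
            "snp": kept_snps,
            "beta_exposure": bx,
            "se_exposure": se_x,
            "beta_outcome": by,
            "se_outcome": se_y,
            "n": n,
        }
    )


def _validate_summaries(summaries: pd.DataFrame, min_k: int, op: str) -> pd.DataFrame:
    needed = {"snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
    missing = needed - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    if len(summaries) < min_k:
        raise ValueError(f"{op} requires at least {min_k} SNP summaries, got {len(summaries)}")
    if (summaries["se_exposure"] <= 0).any() or (summaries["se_outcome"] <= 0).any():
        raise ValueError("summary standard errors must be positive")
    return summaries.reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary-data estimators
# ---------------------------------------------------------------------------

def wald_ratio(summary) -> MREstimate:
    """Single-SNP causal estimate beta_outcome / beta_exposure.

    SE by the first-order delta method, se_outcome / |beta_exposure|
    (uncertainty in the exposure association ignored, as usual when the
    instrument association is strong).
    """
    bx = float(summary["beta_exposure"])
    by = float(summary["beta_outcome"])
    sy = float(summary["se_outcome"])
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined: beta_exposure is zero")
    beta = by / bx
    se = sy / abs(bx)
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MREstimate(f"wald_{summary.get('snp', '')}".rstrip("_"), beta, se, lo, hi, float(p))


def _ratios_weights(summaries: pd.DataFrame):
    bx = summaries["beta_exposure"].to_numpy(dtype=float)
    by = summaries["beta_outcome"].to_numpy(dtype=float)
    sy = summaries["se_outcome"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ZeroDivisionError("beta_exposure of zero makes a Wald ratio undefined")
    ratios = by / bx
    weights = bx**2 / sy**2  # inverse first-order variance of each ratio
    return ratios, weights


def ivw(summaries: pd.DataFrame) -> tuple[MREstimate, HeterogeneityResult]:
    """Fixed-effect inverse-variance-weighted mean of the Wald ratios.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2), se = sqrt(1/sum(bx^2/sy^2)) —
    algebraically the precision-weighted mean of per-SNP Wald ratios, and
    asymptotically equal to 2SLS with an unweighted continuous allele score
    when the SNPs are uncorrelated. Also returns Cochran's Q about the IVW
    estimate.
    """
    summaries = _validate_summaries(summaries, 2, "ivw")
    ratios, w = _ratios_weights(summaries)
    beta = float((w * ratios).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    p = 2 * stats.norm.sf(abs(beta) / se)
    het = cochran_q(summaries, beta)
    return MREstimate("ivw", beta, se, lo, hi, float(p)), het


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, cum, r))


def weighted_median(
    summaries: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios (robust to <50% invalid SNPs).

    Ratios are ordered and the estimate taken where the standardized
    cumulative inverse-variance weight crosses one half, interpolating
    linearly between bracketing ratios. SE by a seeded parametric bootstrap:
    the summary betas are redrawn from N(beta, se) ``n_boot`` times and the
    weighted median recomputed; CI is the normal interval with that SE.
    """
    summaries = _validate_summaries(summaries, 3, "weighted_median")
    ratios, w = _ratios_weights(summaries)
    beta = _weighted_median_point(ratios, w)
    if n_boot == 0:
        return MREstimate("weighted_median", beta, float("nan"), float("nan"),
                          float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    bx = summaries["beta_exposure"].to_numpy(dtype=float)
    by = summaries["beta_outcome"].to_numpy(dtype=float)
    sx = summaries["se_exposure"].to_numpy(dtype=float)
    sy = summaries["se_outcome"].to_numpy(dtype=float)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        draws[b] = _weighted_median_point(by_b / bx_b, bx_b**2 / sy**2)
    se = float(np.std(draws, ddof=1))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MREstimate("weighted_median", beta, se, lo, hi, float(p))


def mr_egger(summaries: pd.DataFrame) -> tuple[EggerResult, HeterogeneityResult]:
    """MR-Egger: weighted regression of outcome betas on exposure betas.

    Summaries are first oriented so every beta_exposure is non-negative
    (flipping beta_outcome jointly), which makes the intercept interpretable
    as the average directional pleiotropic effect per allele. The regression
    is weighted by 1/se_outcome^2; slope = pleiotropy-adjusted causal
    estimate, intercept = average directional pleiotropy, with t-based CIs
    on K-2 degrees of freedom. Also returns the heterogeneity statistic
    about the Egger fit (weighted residual sum of squares, K-2 df).
    """
    summaries = _validate_summaries(summaries, 3, "mr_egger")
    bx = summaries["beta_exposure"].to_numpy(dtype=float).copy()
    by = summaries["beta_outcome"].to_numpy(dtype=float).copy()
    sy = summaries["se_outcome"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    if np.ptp(bx) == 0:
        raise ValueError("MR-Egger needs spread in the exposure betas")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    A = X.T @ WX
    coef = np.linalg.solve(A, WX.T @ by)
    resid = by - X @ coef
    k = len(bx)
    rss_w = float((w * resid**2).sum())
    sigma2 = rss_w / (k - 2)
    cov = sigma2 * np.linalg.inv(A)
    ses = np.sqrt(np.diag(cov))
    out = []
    for name, b, s in (("egger_intercept", coef[0], ses[0]), ("egger_slope", coef[1], ses[1])):
        lo, hi, p = t_ci_p(float(b), float(s), k - 2)
        out.append(MREstimate(name, float(b), float(s), lo, hi, p))
    het = HeterogeneityResult(rss_w, k - 2, float(stats.chi2.sf(rss_w, k - 2)))
    return EggerResult(slope=out[1], intercept=out[0]), het


def cochran_q(summaries: pd.DataFrame, beta_ref: float) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about a reference causal estimate.

    Q = sum w_j (ratio_j - beta_ref)^2 with w_j the inverse delta-method
    variance of ratio_j; chi-square with K-1 df under homogeneity.
    """
    summaries = _validate_summaries(summaries, 2, "cochran_q")
    ratios, w = _ratios_weights(summaries)
    Q = float((w * (ratios - beta_ref) ** 2).sum())
    df = len(ratios) - 1
    return HeterogeneityResult(Q, df, float(stats.chi2.sf(Q, df)))


def mr_presso(
    summaries: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier test, distortion test.

    The observed statistic is the weighted residual sum of squares of each
    SNP's outcome beta about its leave-one-out IVW prediction. Its null
    distribution comes from ``n_sim`` parametric simulations redrawing
    beta_outcome from N(bx_j * beta_loo_j, se_outcome_j). Per-SNP outlier
    p-values compare each observed squared residual with its simulated
    distribution (Bonferroni-adjusted across SNPs); flagged outliers are
    removed and the IVW estimate recomputed. The distortion p compares the
    observed before/after IVW shift against the same shift in the null
    simulations with the identical SNPs removed.
    """
    summaries = _validate_summaries(summaries, 4, "mr_presso")
    bx = summaries["beta_exposure"].to_numpy(dtype=float)
    by = summaries["beta_outcome"].to_numpy(dtype=float)
    sy = summaries["se_outcome"].to_numpy(dtype=float)
    k = len(bx)
    w = bx**2 / sy**2
    num = bx * by / sy**2
    Sw, Sn = w.sum(), num.sum()
    beta_loo = (Sn - num) / (Sw - w)
    resid2 = ((by - bx * beta_loo) / sy) ** 2
    rss_obs = float(resid2.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(bx * beta_loo, sy, size=(n_sim, k))
    num_s = bx * by_sim / sy**2
    beta_loo_s = (num_s.sum(axis=1, keepdims=True) - num_s) / (Sw - w)
    resid2_s = ((by_sim - bx * beta_loo_s) / sy) ** 2
    rss_sim = resid2_s.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    p_out = (1 + (resid2_s >= resid2).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_out * k, 1.0)
    outlier_p = pd.Series(p_adj, index=summaries["snp"].tolist(), name="outlier_p")
    outlier_mask = p_adj < outlier_alpha
    outliers = summaries.loc[outlier_mask, "snp"].tolist()

    est_before, _ = ivw(summaries)
    est_before = replace(est_before, method="presso_raw")
    est_after = None
    distortion_p = float("nan")
    if outlier_mask.any() and (~outlier_mask).sum() >= 2:
        est_after, _ = ivw(summaries.loc[~outlier_mask])
        est_after = replace(est_after, method="presso_corrected")
        d_obs = est_after.beta - est_before.beta
        ivw_before_s = num_s.sum(axis=1) / Sw
        keep = ~outlier_mask
        ivw_after_s = num_s[:, keep].sum(axis=1) / w[keep].sum()
        d_sim = ivw_after_s - ivw_before_s
        distortion_p = float((1 + (np.abs(d_sim) >= abs(d_obs)).sum()) / (n_sim + 1))
    return PressoResult(
        global_rss_observed=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        distortion_p=distortion_p,
        estimate_before=est_before,
        estimate_after=est_after,
    )


def leave_one_out(summaries: pd.DataFrame) -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn.

    One row per excluded SNP: the IVW estimate, CI, p and Cochran's Q of the
    remaining K-1 summaries. A SNP whose exclusion collapses Q is the
    heterogeneity driver.
    """
    summaries = _validate_summaries(summaries, 3, "leave_one_out")
    rows = []
    for j in range(len(summaries)):
        rest = summaries.drop(index=j)
        est, het = ivw(rest)
        rows.append(
            {"excluded_snp": summaries.loc[j, "snp"], "beta": est.beta, "se": est.se,
             "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
             "Q": het.Q, "q_df": het.df, "q_p": het.p}
        )
    return pd.DataFrame(rows)
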
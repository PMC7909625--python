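"""SNP quality control, replication filtering and genetic-risk-score building.

The instrument for Mendelian randomization is an unweighted allele count
over menarche-associated SNPs, oriented so that a higher score predicts
*earlier* menarche. Candidate SNPs pass array-style genotype QC (call rate,
minor allele frequency, Hardy-Weinberg equilibrium), must replicate their
published AAM association in-sample (p below alpha with the published sign),
and can be dropped by an explicit exclusion list when external evidence
flags pleiotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import add_intercept, check_full_rank, ols, t_ci_p
from .simulate import CohortData

__all__ = [
    "QCCriteria",
    "QCResult",
    "FirstStageDiagnostics",
    "hwe_test",
    "hwe_exact_test",
    "qc_filter_snps",
    "replicate_snps",
    "build_grs",
    "grs_quartiles",
    "first_stage_diagnostics",
    "confounder_balance",
]


@dataclass
class QCCriteria:
    """Genotype QC thresholds (array-QC convention: strict > comparisons)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_sample_call_rate: float = 0.90

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def hwe_test(counts) -> float:
    """Hardy-Weinberg equilibrium chi-square goodness-of-fit p-value.

    ``counts`` is the genotype count triple (hom_effect, het, hom_other).
    One degree of freedom (three classes, one estimated allele frequency).
    A monomorphic SNP is in HWE by convention (p = 1).
    """
    n2, n1, n0 = (int(c) for c in counts)
    n = n2 + n1 + n0
    if n < 1:
        raise ValueError("HWE test needs at least one genotyped sample")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n2, n1, n0], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(counts) -> float:
    """Exact Hardy-Weinberg test (conditional heterozygote distribution).

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, conditional on the allele counts.
    """
    n2, n1, n0 = (int(c) for c in counts)
    n = n2 + n1 + n0
    if n < 1:
        raise ValueError("HWE test needs at least one genotyped sample")
    n_a = 2 * n2 + n1  # effect-allele count
    n_b = 2 * n0 + n1
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant
    from scipy.special import gammaln

    def logprob(h):
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        return (
            h * np.log(2.0)
            - gammaln(h + 1)
            - gammaln(hom_a + 1)
            - gammaln(hom_b + 1)
        )

    logs = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hets == n1][0]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    valid = col[~np.isnan(col)]
    return int((valid == 2).sum()), int((valid == 1).sum()), int((valid == 0).sum())


@dataclass
class QCResult:
    retained: list[str]
    report: pd.DataFrame
    dropped_samples: list[str] = field(default_factory=list)


def qc_filter_snps(
    genotypes: pd.DataFrame, criteria: QCCriteria | None = None, exact_hwe: bool = False
) -> QCResult:
    """Apply per-sample then per-SNP genotype QC.

    Samples whose call rate is at or below ``min_sample_call_rate`` are
    dropped first; each SNP is then retained iff call rate > ``min_call_rate``,
    MAF > ``min_maf`` and HWE p > ``min_hwe_p``. The report lists every SNP's
    metrics with a pass/fail status and the failed criteria.
    """
    if genotypes.shape[0] == 0 or genotypes.shape[1] == 0:
        raise ValueError("genotype matrix is empty")
    criteria = criteria or QCCriteria()
    G = genotypes.to_numpy(dtype=float)
    sample_call = 1.0 - np.isnan(G).mean(axis=1)
    keep_samples = sample_call > criteria.min_sample_call_rate
    if not keep_samples.any():
        raise ValueError("all samples dropped by the sample call-rate filter")
    dropped = [str(s) for s in genotypes.index[~keep_samples]]
    G = G[keep_samples]

    hwe = hwe_exact_test if exact_hwe else hwe_test
    rows = []
    for j, snp in enumerate(genotypes.columns):
        col = G[:, j]
        call_rate = 1.0 - float(np.isnan(col).mean())
        valid = col[~np.isnan(col)]
        if len(valid) == 0:
            freq, maf, hwe_p = np.nan, 0.0, 1.0
        else:
            freq = float(valid.mean() / 2.0)
            maf = min(freq, 1.0 - freq)
            hwe_p = hwe(_genotype_counts(col))
        reasons = []
        if not call_rate > criteria.min_call_rate:
            reasons.append("call_rate")
        if not maf > criteria.min_maf:
            reasons.append("maf")
        if not hwe_p > criteria.min_hwe_p:
            reasons.append("hwe")
        rows.append(
            {
                "snp": snp,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "status": "pass" if not reasons else "fail",
                "reason": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    retained = report.loc[report["status"] == "pass", "snp"].tolist()
    return QCResult(retained=retained, report=report, dropped_samples=dropped)


def replicate_snps(
    candidates: pd.DataFrame,
    data: CohortData,
    alpha: float = 0.05,
    exclusions: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Keep candidate SNPs that replicate their published AAM association.

    Per SNP, an unadjusted regression of AAM on allele dosage must reach
    ``p < alpha`` with a coefficient sign matching ``published_direction``.
    SNPs on the explicit exclusion list (external pleiotropy evidence) are
    then removed. Returns the filtered panel with the in-sample beta/se/p
    appended.
    """
    aam = data.phenotypes["aam"].to_numpy(dtype=float)
    missing = [s for s in candidates["snp"] if s not in data.genotypes.columns]
    if missing:
        raise KeyError(f"candidate SNP(s) absent from genotype matrix: {missing}")
    kept = []
    for _, row in candidates.iterrows():
        dose = data.genotypes[row["snp"]].to_numpy(dtype=float)
        mask = ~np.isnan(dose)
        if dose[mask].std() == 0:
            continue
        X = add_intercept(dose[mask][:, None], int(mask.sum()))
        coef, se, _, df = ols(aam[mask], X)
        _, _, p = t_ci_p(coef[1], se[1], df)
        if p < alpha and np.sign(coef[1]) == np.sign(row["published_direction"]):
            rec = dict(row)
            rec.update(beta_replication=float(coef[1]), se_replication=float(se[1]), p_replication=p)
            kept.append(rec)
    out = pd.DataFrame(kept, columns=list(candidates.columns) + [
        "beta_replication", "se_replication", "p_replication"])
    out = out[~out["snp"].isin(set(exclusions))].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("no candidate SNPs survived replication filtering", stacklevel=2)
    return out


def build_grs(genotypes: pd.DataFrame, panel: pd.DataFrame) -> pd.Series:
    """Unweighted count of menarche-advancing alleles.

    For SNPs whose effect allele *increases* AAM (published_direction +1) the
    dosage is flipped to ``2 - G`` so every counted allele pushes menarche
    earlier; higher GRS therefore predicts younger AAM. Missing dosages are
    mean-imputed per SNP after orientation.
    """
    missing = [s for s in panel["snp"] if s not in genotypes.columns]
    if missing:
        raise KeyError(f"panel SNP(s) absent from genotype matrix: {missing}")
    total = np.zeros(len(genotypes))
    for _, row in panel.iterrows():
        dose = genotypes[row["snp"]].to_numpy(dtype=float)
        if row["published_direction"] > 0:
            dose = 2.0 - dose
        nan = np.isnan(dose)
        if nan.any():
            fill = np.nanmean(dose) if not nan.all() else 0.0
            dose = np.where(nan, fill, dose)
        total += dose
    return pd.Series(total, index=genotypes.index, name="grs")


def grs_quartiles(grs) -> np.ndarray:
    """Rank-based quartiles 1-4; ties share the lower quartile."""
    values = np.asarray(grs, dtype=float)
    if len(np.unique(values)) < 4:
        raise ValueError("need at least 4 distinct GRS values to form quartiles")
    ranks = stats.rankdata(values, method="min")
    return np.ceil(4.0 * ranks / len(values)).astype(int)


@dataclass
class FirstStageDiagnostics:
    """Instrument-strength summary of the exposure-on-GRS regression."""

    coef_per_unit: float
    ci_per_unit: tuple[float, float]
    p_per_unit: float
    coef_per_quartile: float
    ci_per_quartile: tuple[float, float]
    p_per_quartile: float
    F: float
    F_quartile: float
    R2: float
    R2_quartile: float
    n: int


def _partial_fit(y, inst, covars, names):
    """Fit y ~ [1, covars, inst]; return coef stats plus partial F and R2."""
    n = len(y)
    X_r = add_intercept(covars, n)
    X_f = np.hstack([X_r, np.asarray(inst, dtype=float)[:, None]])
    check_full_rank(X_f, ["const"] + names + ["instrument"])
    coef, se, rss_f, df_f = ols(y, X_f)
    _, _, rss_r, _ = ols(y, X_r)
    ci_low, ci_high, p = t_ci_p(coef[-1], se[-1], df_f)
    # Partial F of the single instrument term; with no covariates this
    # reduces to the textbook F = (n-2) R^2 / (1 - R^2).
    F = (rss_r - rss_f) / (rss_f / df_f)
    R2 = (rss_r - rss_f) / rss_r if rss_r > 0 else 0.0
    return float(coef[-1]), (ci_low, ci_high), p, float(F), float(R2)


def first_stage_diagnostics(
    data: CohortData,
    grs,
    covariates: pd.DataFrame | None = None,
    exposure: str = "aam",
) -> FirstStageDiagnostics:
    """F / R-squared diagnostics of the GRS as an instrument for the exposure.

    The exposure is regressed on the GRS continuously and, separately, on its
    quartile code (1-4, entered linearly, matching the per-quartile-increase
    reporting convention). F is the instrument's partial F over the covariate
    set; R2 the corresponding partial R-squared.
    """
    y = data.phenotypes[exposure].to_numpy(dtype=float)
    cov = None
    names: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.to_numpy(dtype=float)
        names = [str(c) for c in covariates.columns]
    grs = np.asarray(grs, dtype=float)
    if len(grs) != len(y):
        raise ValueError("GRS length does not match phenotype table")
    b_u, ci_u, p_u, F_u, R2_u = _partial_fit(y, grs, cov, names)
    quart = grs_quartiles(grs).astype(float)
    b_q, ci_q, p_q, F_q, R2_q = _partial_fit(y, quart, cov, names)
    return FirstStageDiagnostics(
        coef_per_unit=b_u, ci_per_unit=ci_u, p_per_unit=p_u,
        coef_per_quartile=b_q, ci_per_quartile=ci_q, p_per_quartile=p_q,
        F=F_u, F_quartile=F_q, R2=R2_u, R2_quartile=R2_q, n=len(y),
    )


def confounder_balance(data: CohortData, grs, confounders: list[str]) -> pd.DataFrame:
    """Association of each putative confounder with the GRS.

    Each confounder is regressed on the GRS (ordinal/categorical confounders
    enter as their numeric codes, i.e. a linear trend test), reported as the
    change per 1-unit GRS increase with a 95% CI and p-value. An instrument
    satisfying the independence assumption shows coefficients near zero.
    """
    rows = []
    grs = np.asarray(grs, dtype=float)
    for name in confounders:
        y = pd.to_numeric(
            data.phenotypes[name], errors="coerce"
        ).to_numpy(dtype=float)
        mask = ~np.isnan(y)
        X = add_intercept(grs[mask][:, None], int(mask.sum()))
        coef, se, _, df = ols(y[mask], X)
        lo, hi, p = t_ci_p(coef[1], se[1], df)
        rows.append(
            {"confounder": name, "beta_per_grs": float(coef[1]), "se": float(se[1]),
             "ci_low": lo, "ci_high": hi, "p": p, "n": int(mask.sum())}
        )
    return pd.DataFrame(rows, columns=[
        "confounder", "beta_per_grs", "se", "ci_low", "ci_high", "p", "n"])
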
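"""Synthetic cohort and reference-population generator.

Everything downstream (cohort segmentation, generation standardization,
instrument construction, the MR estimator suite) is validated against data
produced here, where the causal effect of age at menarche (AAM) on
young-adult BMI and every violation of the instrumental-variable assumptions
are known exactly.

Generative model, per individual i with birth year y_i and genotype dosage
G_ij in {0,1,2} at SNP j (Hardy-Weinberg proportions, independent SNPs):

    educ_i ~ Categorical(p(y_i))                (later cohorts more educated)
    AAM_i  = trend(y_i) + sum_j effect_j G_ij
             + educ_effect_on_aam * educ_i + N(0, aam_noise_sd)
    BMI_i  = beta_causal * AAM_i + sum_j alpha_j G_ij
             + educ_effect_on_bmi * educ_i + bmi_shift(y_i) + N(0, bmi_noise_sd)

alpha_j are direct (pleiotropic) SNP->BMI effects, zero by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "simulate_reference_population",
    "simulate_cohort",
    "true_parameters",
    "education_probabilities",
    "EARLY_MENARCHE_CUTOFF",
]

#: AAM strictly below this age counts as "early menarche" (years).
EARLY_MENARCHE_CUTOFF = 14.0

# Education codebook probabilities at the two ends of the default birth-year
# span; intermediate years interpolate linearly. Oldest cohorts are mostly
# at/below elementary schooling, the youngest mostly high-school/university.
_EDU_P_OLD = np.array([0.45, 0.30, 0.15, 0.08, 0.02])
_EDU_P_NEW = np.array([0.01, 0.02, 0.07, 0.35, 0.55])


def education_probabilities(birth_year, year_range: tuple[int, int]) -> np.ndarray:
    """Per-year categorical probabilities over the 5 education levels."""
    start, end = year_range
    y = np.asarray(birth_year, dtype=float)
    span = max(end - start, 1)
    frac = np.clip((y - start) / span, 0.0, 1.0)[..., None]
    p = (1.0 - frac) * _EDU_P_OLD + frac * _EDU_P_NEW
    return p / p.sum(axis=-1, keepdims=True)


def _sample_education(years: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    probs = education_probabilities(years, cfg.birth_year_range)
    u = rng.random(len(years))
    cum = np.cumsum(probs, axis=1)
    return 1 + (u[:, None] > cum).sum(axis=1)


def simulate_reference_population(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a per-birth-year AAM reference table.

    Emulates a large population survey used purely as the standardization
    substrate: for each birth year in range, ``n_individuals`` AAM values are
    drawn around the secular trend (no genetic or education structure — the
    reference characterizes the marginal AAM distribution of the year).

    Returns a DataFrame with columns ``birth_year, mean_aam, sd_aam,
    prop_early, n`` — one row per year, years contiguous.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start, end = config.birth_year_range
    years = np.arange(start, end + 1)
    trend = config.trend_fn()
    rows = []
    for y in years:
        aam = trend(np.full(config.n_individuals, y)) + rng.normal(
            0.0, config.aam_noise_sd, config.n_individuals
        )
        rows.append(
            {
                "birth_year": int(y),
                "mean_aam": float(aam.mean()),
                "sd_aam": float(aam.std(ddof=1)) if len(aam) > 1 else 0.0,
                "prop_early": float((aam < EARLY_MENARCHE_CUTOFF).mean()),
                "n": int(len(aam)),
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> tuple["CohortData", pd.DataFrame]:
    """Simulate a study cohort plus its SNP instrument panel.

    Returns
    -------
    data : CohortData
        Phenotype table and 0/1/2 genotype dosage matrix.
    panel : DataFrame
        Per-SNP ``snp, effect_allele, published_direction, effect_allele_freq``;
        ``published_direction`` is the sign of the configured AAM effect, i.e.
        the direction an external discovery study would have reported.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    start, end = config.birth_year_range

    years = rng.integers(start, end + 1, size=n)
    genotypes = rng.binomial(2, config.effect_allele_freqs, size=(n, m)).astype(float)
    education = _sample_education(years, config, rng)

    trend = config.trend_fn()
    aam = (
        trend(years)
        + genotypes @ config.snp_effects_on_aam
        + config.educ_effect_on_aam * education
        + rng.normal(0.0, config.aam_noise_sd, n)
    )
    bmi = (
        config.beta_causal * aam
        + genotypes @ config.pleiotropy_effects
        + config.educ_effect_on_bmi * education
        + config.bmi_shift_fn()(years)
        + rng.normal(0.0, config.bmi_noise_sd, n)
    )

    if config.genotype_missing_rate > 0:
        mask = rng.random((n, m)) < config.genotype_missing_rate
        genotypes[mask] = np.nan

    snp_ids = [f"rs{1000 + 17 * j}" for j in range(m)]
    alleles = np.array(list("ACGT"))[rng.integers(0, 4, size=m)]
    pheno = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "birth_year": years.astype(int),
            "aam": aam,
            "education": education.astype(int),
            "bmi_young_adult": bmi,
        }
    )
    geno = pd.DataFrame(genotypes, columns=snp_ids, index=pheno["id"])
    panel = pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": alleles,
            "published_direction": np.where(config.snp_effects_on_aam > 0, 1, -1).astype(int),
            "effect_allele_freq": config.effect_allele_freqs,
        }
    )
    return CohortData(phenotypes=pheno, genotypes=geno), panel


@dataclass
class CohortData:
    """A study cohort: phenotype table plus genotype dosage matrix.

    ``phenotypes`` columns: id, birth_year, aam, education, bmi_young_adult
    (standardized columns gsaam / cohort / highly_educated / grs are appended
    by later pipeline stages). ``genotypes`` is individuals x SNPs with
    entries in {0, 1, 2} or NaN for missing calls.
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.phenotypes) != len(self.genotypes):
            raise ValueError("phenotype and genotype tables disagree on sample count")


def true_parameters(config: SimulationConfig) -> dict:
    """Ground-truth record for parameter-recovery tests."""
    config.validate()
    return {
        "beta_causal": float(config.beta_causal),
        "snp_effects_on_aam": [float(v) for v in config.snp_effects_on_aam],
        "pleiotropy_effects": [float(v) for v in config.pleiotropy_effects],
        "educ_effect_on_aam": float(config.educ_effect_on_aam),
        "educ_effect_on_bmi": float(config.educ_effect_on_bmi),
        "seed": int(config.seed),
    }
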
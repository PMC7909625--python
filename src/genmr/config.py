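"""Simulation configuration for synthetic menarche/BMI cohorts.

The generative model is the linear causal diagram the analysis targets:
genotypes and education shift age at menarche (AAM), AAM causally shifts
young-adult BMI, and birth year drives a secular trend in both the AAM
distribution and the education distribution. Pleiotropy (direct SNP->BMI
effects) can be switched on to violate the exclusion restriction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = ["SimulationConfig", "EDUCATION_LEVELS"]

#: 5-level education codebook, ordinal 1..5.
EDUCATION_LEVELS = {
    1: "under elementary school",
    2: "elementary school",
    3: "middle school",
    4: "high school",
    5: "university/college or higher",
}

# Default secular decline of mean AAM: 16.5 years for the 1927 birth year
# falling linearly to 12.4 years by 2003 (the observed Korean-cohort scale).
_TREND_START_YEAR, _TREND_END_YEAR = 1927, 2003
_TREND_START_AAM, _TREND_END_AAM = 16.5, 12.4

# Default generational BMI baseline: young-adult BMI was higher in older
# generations (~21.8 kg/m2 for the oldest cohort, ~20.5 for the youngest).
_BMI_START, _BMI_END = 21.8, 20.5


def default_secular_trend(birth_year) -> np.ndarray:
    """Linear interpolation 16.5 y (1927) -> 12.4 y (2003), clamped outside."""
    y = np.asarray(birth_year, dtype=float)
    frac = np.clip((y - _TREND_START_YEAR) / (_TREND_END_YEAR - _TREND_START_YEAR), 0.0, 1.0)
    return _TREND_START_AAM + frac * (_TREND_END_AAM - _TREND_START_AAM)


def default_cohort_bmi_shift(birth_year) -> np.ndarray:
    """Linear generational BMI baseline 21.8 -> 20.5 kg/m2 over 1927-2003."""
    y = np.asarray(birth_year, dtype=float)
    frac = np.clip((y - _TREND_START_YEAR) / (_TREND_END_YEAR - _TREND_START_YEAR), 0.0, 1.0)
    return _BMI_START + frac * (_BMI_END - _BMI_START)


def _default_freqs() -> np.ndarray:
    # 14 effect-allele frequencies spread over the common range.
    return np.linspace(0.15, 0.45, 14)


def _default_aam_effects() -> np.ndarray:
    # Per-allele AAM shifts in years, all menarche-delaying-allele oriented
    # negative (effect allele brings menarche earlier); spread so MR-Egger
    # has exposure-beta leverage.
    return np.linspace(-0.12, -0.04, 14)


def _as_trend(spec) -> Callable[[np.ndarray], np.ndarray]:
    """Accept a callable, a {year: value} mapping, or a constant."""
    if callable(spec):
        return spec
    if isinstance(spec, Mapping):
        years = np.array(sorted(spec), dtype=float)
        vals = np.array([spec[int(y)] for y in years], dtype=float)

        def interp(birth_year):
            return np.interp(np.asarray(birth_year, dtype=float), years, vals)

        return interp
    const = float(spec)
    return lambda birth_year: np.full_like(np.asarray(birth_year, dtype=float), const)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator.

    Parameters
    ----------
    n_individuals
        Cohort size (also the per-birth-year sample size when simulating a
        reference population).
    birth_year_range
        Inclusive (start, end) birth years.
    effect_allele_freqs, snp_effects_on_aam
        Per-SNP effect-allele frequency in (0, 1) and per-allele AAM shift in
        years (negative = earlier menarche).
    beta_causal
        True causal effect of AAM on young-adult BMI, kg/m2 per year.
    pleiotropy_effects
        Per-SNP direct effect on BMI, kg/m2 per allele (all zero by default:
        valid instruments).
    educ_effect_on_aam, educ_effect_on_bmi
        Confounding path: years of AAM (resp. kg/m2 of BMI) per one education
        level.
    secular_trend, cohort_bmi_shift
        Callables/mappings/constants giving the birth-year baseline of mean
        AAM and of BMI.
    aam_noise_sd, bmi_noise_sd
        Gaussian noise SDs (years, kg/m2).
    genotype_missing_rate
        Probability an individual genotype call is missing (default 0).
    """

    n_individuals: int = 10_000
    birth_year_range: tuple[int, int] = (1927, 2003)
    n_snps: int = 14
    effect_allele_freqs: Sequence[float] = field(default_factory=_default_freqs)
    snp_effects_on_aam: Sequence[float] = field(default_factory=_default_aam_effects)
    beta_causal: float = 0.0
    pleiotropy_effects: Sequence[float] | None = None
    educ_effect_on_aam: float = -0.10
    educ_effect_on_bmi: float = -0.20
    secular_trend: object = default_secular_trend
    aam_noise_sd: float = 1.6
    bmi_noise_sd: float = 2.8
    cohort_bmi_shift: object = default_cohort_bmi_shift
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_allele_freqs = np.asarray(self.effect_allele_freqs, dtype=float)
        self.snp_effects_on_aam = np.asarray(self.snp_effects_on_aam, dtype=float)
        if self.pleiotropy_effects is None:
            self.pleiotropy_effects = np.zeros(self.n_snps)
        self.pleiotropy_effects = np.asarray(self.pleiotropy_effects, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        start, end = self.birth_year_range
        if end < start:
            raise ValueError(
                f"degenerate birth_year_range: end {end} < start {start}"
            )
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("effect_allele_freqs", "snp_effects_on_aam", "pleiotropy_effects"):
            vec = getattr(self, name)
            if len(vec) != self.n_snps:
                raise ValueError(
                    f"{name} has length {len(vec)}, expected n_snps={self.n_snps}"
                )
        f = self.effect_allele_freqs
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("effect_allele_freqs must lie strictly in (0, 1)")
        if self.aam_noise_sd < 0 or self.bmi_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.genotype_missing_rate < 1.0:
            raise ValueError("genotype_missing_rate must be in [0, 1)")

    # -- trend accessors ---------------------------------------------------
    def trend_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        return _as_trend(self.secular_trend)

    def bmi_shift_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        return _as_trend(self.cohort_bmi_shift)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("effect_allele_freqs", "snp_effects_on_aam", "pleiotropy_effects"):
            d[key] = [float(v) for v in d[key]]
        d["birth_year_range"] = list(self.birth_year_range)
        for key in ("secular_trend", "cohort_bmi_shift"):
            val = d[key]
            if callable(val):
                # Tabulate callables over the birth-year range so configs
                # round-trip through flat files.
                years = np.arange(self.birth_year_range[0], self.birth_year_range[1] + 1)
                fn = self.trend_fn() if key == "secular_trend" else self.bmi_shift_fn()
                d[key] = {int(y): float(v) for y, v in zip(years, fn(years))}
            elif isinstance(val, Mapping):
                d[key] = {int(k): float(v) for k, v in val.items()}
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "birth_year_range" in d:
            d["birth_year_range"] = tuple(int(v) for v in d["birth_year_range"])
        for key in ("secular_trend", "cohort_bmi_shift"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)
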
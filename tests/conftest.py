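import numpy as np
import pandas as pd
import pytest

from genmr import SimulationConfig, simulate_cohort, simulate_reference_population


@pytest.fixture(scope="session")
def small_config():
    """A quick cohort: strong SNP effects so replication works at small n."""
    return SimulationConfig(
        n_individuals=1500,
        birth_year_range=(1950, 1969),
        n_snps=6,
        effect_allele_freqs=np.linspace(0.2, 0.45, 6),
        snp_effects_on_aam=np.linspace(-0.45, -0.25, 6),
        beta_causal=-0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_reference(small_config):
    ref_cfg = SimulationConfig(
        n_individuals=4000,
        birth_year_range=small_config.birth_year_range,
        n_snps=small_config.n_snps,
        effect_allele_freqs=small_config.effect_allele_freqs,
        snp_effects_on_aam=small_config.snp_effects_on_aam,
        seed=8,
    )
    return simulate_reference_population(ref_cfg)


def make_summaries(
    rng=None,
    beta: float = -0.5,
    k: int = 14,
    sy: float = 0.04,
    sx: float = 0.005,
    outlier: int | None = None,
    noise: bool = True,
):
    """Parametric per-SNP summary table with known causal slope."""
    rng = rng or np.random.default_rng(0)
    bx = np.linspace(-0.12, -0.04, k)
    by = bx * beta + (rng.normal(0.0, sy, k) if noise else 0.0)
    if outlier is not None:
        by[outlier] += 10 * sy
    return pd.DataFrame(
        {
            "snp": [f"rs{j}" for j in range(k)],
            "beta_exposure": bx,
            "se_exposure": np.full(k, sx),
            "beta_outcome": by,
            "se_outcome": np.full(k, sy),
        }
    )
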
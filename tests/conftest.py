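import numpy as np
import pandas as pd
import pytest

from cohortsel import SimulationConfig, make_panel, simulate_individuals
from cohortsel.simulate import default_aging_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_aging_schedule(delta_per_5y=0.10)


@pytest.fixture(scope="session")
def null_config():
    """Small all-null study: 12 SNPs, no selection, no trait effects."""
    rng = np.random.default_rng(42)
    m = 12
    zeros = np.zeros(m)
    return SimulationConfig(
        n_per_cohort=400, baseline_freqs=rng.uniform(0.2, 0.8, m),
        s_true=zeros, u_true=zeros, beta_afb=zeros, beta_neb=zeros,
        beta_lifespan=zeros, h2=0.35, env_trend_per_year=0.0,
        missing_rate=0.02, pool_size=200, seed=42)


@pytest.fixture(scope="session")
def null_dataset(null_config):
    panel = make_panel(null_config)
    return simulate_individuals(panel, null_config), panel


@pytest.fixture()
def covariate_frame():
    """Phenotype-like frame with age/sex/PC covariate columns."""
    rng = np.random.default_rng(3)
    n = 500
    return pd.DataFrame({
        "exam_age": rng.integers(40, 70, n).astype(float),
        "sex": rng.integers(0, 2, n),
        **{f"pc{i}": rng.standard_normal(n) for i in range(1, 11)},
    })
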
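import warnings

import numpy as np
import pandas as pd
import pytest

from searchimpact.synthetic import (
    SimulationConfig,
    simulate_covariates,
    simulate_response,
    simulate_study_panel,
)

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A compact data-generating configuration used across modules."""
    return SimulationConfig(
        n_pre=72,
        n_post=12,
        trend_spec="local_level",
        true_support=(),
        seasonal_amplitude=3.0,
        noise_sd=1.0,
        level_sd=0.3,
        seed=11,
        start_month="2013-01-01",
    )


@pytest.fixture(scope="session")
def small_series(small_config):
    cov = simulate_covariates(small_config)
    synth = simulate_response(small_config, cov)
    return synth


@pytest.fixture(scope="session")
def toy_panel():
    """Two countries x two terms, 96+12 months, one injected step effect."""
    cfg = SimulationConfig(
        n_pre=96,
        n_post=12,
        trend_spec="local_linear",
        true_support=("une",),
        true_coefficients={"une": 1.0},
        noise_sd=1.0,
        level_sd=0.2,
        slope_sd=0.01,
        seasonal_amplitude=2.0,
        seed=21,
        start_month="2012-07-01",
        covid_breakpoint=96,  # pandemic series switch on at the intervention
    )
    return simulate_study_panel(
        cfg,
        ["AAA", "BBB"],
        ["alpha", "beta"],
        effects={("AAA", "alpha"): 15.0},
    )
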
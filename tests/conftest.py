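import numpy as np
import pytest

from fullcycle import mcmc
from fullcycle.model import ModelConfig, build_ipm_data
from fullcycle.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale simulated data set (26 years, 3-year gap)."""
    cfg = SimulationConfig(seed=2024)
    truth, enc, counts, prod = simulate_dataset(cfg)
    data = build_ipm_data(enc, counts, prod, truth.covariates, cfg.gap_years)
    return cfg, truth, enc, counts, prod, data


@pytest.fixture(scope="session")
def small_dataset():
    """A cheaper 14-year data set without a gap, for fast fitting tests."""
    cfg = SimulationConfig(
        n_years=14,
        gap_years=frozenset(),
        seed=77,
        beta={"phi_ad_f": {"winter_temp": 0.3}, "phi_ad_m": {"winter_temp": 0.3}},
    )
    truth, enc, counts, prod = simulate_dataset(cfg)
    data = build_ipm_data(enc, counts, prod, truth.covariates, cfg.gap_years)
    return cfg, truth, enc, counts, prod, data


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short posterior fit shared by the GOF / derived-quantity tests."""
    cfg, truth, enc, counts, prod, data = small_dataset
    config = ModelConfig(beta_design=[("phi_ad_f", "winter_temp"), ("phi_ad_m", "winter_temp")])
    mc = mcmc.McmcConfig(n_chains=2, n_iter=4000, n_burnin=2000, thin=4, seed=9)
    return mcmc.run_mcmc(data, config, mc)


@pytest.fixture(scope="session")
def study_fit(study_dataset):
    """A short fit of the study-scale data set (gap included)."""
    cfg, truth, enc, counts, prod, data = study_dataset
    config = ModelConfig(
        beta_design=[
            ("phi_j_f", "winter_temp"), ("phi_j_m", "winter_temp"),
            ("phi_ad_f", "winter_temp"), ("phi_ad_m", "winter_temp"),
            ("rho", "breeding_density_detrended"),
            ("iota_f", "winter_temp"), ("iota_m", "winter_temp"),
        ]
    )
    mc = mcmc.McmcConfig(n_chains=2, n_iter=5000, n_burnin=2500, thin=5, seed=31)
    return mcmc.run_mcmc(data, config, mc)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
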
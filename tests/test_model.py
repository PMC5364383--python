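"""Likelihood blocks against closed-form and term-by-term pmf oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from fullcycle.io import MArraySet
from fullcycle.model import (
    IPMData,
    LatentStates,
    ModelConfig,
    ObservationParams,
    RecaptureParams,
    VitalRateParams,
    cjs_cell_probs,
    cjs_loglik,
    joint_log_posterior,
    obs_loglik,
    prior_logdensity,
    productivity_loglik,
    state_loglik,
    vital_rate_series,
)


def test_vital_rate_series_links():
    X = np.ones((1, 1))
    assert vital_rate_series(0.0, {}, X, np.zeros(1), "logit")[0] == pytest.approx(0.5)
    assert vital_rate_series(0.0, {}, X, np.zeros(1), "log")[0] == pytest.approx(1.0)
    got = vital_rate_series(0.5, {0: 0.3}, X, np.array([-0.2]), "logit")[0]
    assert got == pytest.approx(expit(0.6))


def _latents(R, S, I, F_tot, F_f):
    return LatentStates(*(np.asarray(a) for a in (R, S, I, F_tot, F_f)))


def _const_rates(T, phi_j=0.3, phi_ad=0.5, rho=2.0, iota=5.0):
    return {
        "phi_j": np.full((2, T - 1), phi_j),
        "phi_ad": np.full((2, T - 1), phi_ad),
        "rho": np.full(T, rho),
        "iota": np.full((2, T), iota),
    }


def test_state_loglik_impossible_transition_is_neg_inf():
    T = 2
    lat = _latents(
        R=[[5, 30], [5, 0]], S=[[5, 2], [5, 2]], I=[[0, 0], [0, 0]],
        F_tot=[20, 0], F_f=[11, 0],
    )  # R_f,1 = 30 > F_f,0 = 11
    assert state_loglik(lat, _const_rates(T)) == -np.inf


def test_state_loglik_degenerate_binomial_contributes_zero():
    T = 2
    rates = _const_rates(T, phi_ad=1.0, iota=0.0)
    lat = _latents(
        R=[[0, 0], [0, 0]], S=[[10, 10], [8, 8]], I=[[0, 0], [0, 0]],
        F_tot=[0, 0], F_f=[0, 0],
    )
    base = state_loglik(lat, rates)
    assert np.isfinite(base)  # survival-1 binomial terms add exactly log 1 = 0


def test_state_loglik_term_by_term_oracle():
    """Toy year: B_f=10, rho=2 -> F=20; F_f=11; phi_j=0.3, R_f'=4."""
    T = 2
    lat = _latents(
        R=[[0, 4], [0, 0]], S=[[10, 0], [0, 0]], I=[[0, 0], [0, 0]],
        F_tot=[20, 0], F_f=[11, 0],
    )
    rates = _const_rates(T, phi_j=0.3, phi_ad=0.0, rho=2.0, iota=0.0)
    expected = (
        stats.poisson.logpmf(20, 2.0 * 10)      # F ~ Pois(rho * B_f)
        + stats.binom.logpmf(11, 20, 0.5)        # female fledglings
        + stats.binom.logpmf(4, 11, 0.3)         # female recruits
        + stats.binom.logpmf(0, 9, 0.3)          # male recruits
        + stats.binom.logpmf(0, 10, 0.0)         # surviving females
        + stats.poisson.logpmf(0, 2.0 * 4)       # F at t=1 (B_f = 4 recruits)
        + stats.binom.logpmf(0, 0, 0.5)
        + 6 * np.log(1 / 301.0)                  # initial-abundance priors
    )
    assert state_loglik(lat, rates) == pytest.approx(expected, abs=1e-10)


def test_obs_loglik_maximum_and_gap_and_scalar_oracle():
    B = np.array([[100, 90], [50, 60]])
    counts = np.array([[100.0, np.nan], [50.0, np.nan]])  # year 1 unobserved
    sigma = 0.1
    got = obs_loglik(counts, B, sigma)
    assert got == pytest.approx(2 * stats.norm.logpdf(0.0, scale=sigma))
    counts2 = np.array([[100.0, np.nan], [np.nan, np.nan]])
    single = obs_loglik(counts2, np.array([[90, 1], [1, 1]]), sigma)
    assert single == pytest.approx(
        stats.norm.logpdf(np.log(100) - np.log(90), scale=sigma)
    )
    with pytest.raises(ValueError):
        obs_loglik(np.array([[0.0]]), np.array([[5]]), sigma)


def test_cjs_cell_probs():
    cells = cjs_cell_probs(np.array([1.0, 1.0]), np.array([0.0, 1.0, 1.0]), 0)
    assert cells[0] == pytest.approx(1.0)  # certain recapture next occasion
    cells = cjs_cell_probs(np.array([0.5, 0.5]), np.array([0.0, 0.8, 0.8]), 0)
    assert cells == pytest.approx([0.4, 0.04, 0.56])
    rng = np.random.default_rng(0)
    for _ in range(20):
        T = rng.integers(2, 8)
        phi = rng.uniform(0, 1, T - 1)
        p = rng.uniform(0, 1, T)
        i = int(rng.integers(0, T - 1))
        assert cjs_cell_probs(phi, p, i).sum() == pytest.approx(1.0, abs=1e-12)


def _marray_single(T, row_entries, release_occ, group="ad_f"):
    from fullcycle.constants import GROUPS

    ma = MArraySet(n_occasions=T)
    for g in GROUPS:
        ma.m[g] = np.zeros((T - 1, T), dtype=np.int64)
        ma.releases[g] = np.zeros(T - 1, dtype=np.int64)
    for col, n in row_entries.items():
        ma.m[group][release_occ, col] = n
    ma.releases[group][release_occ] = sum(row_entries.values())
    return ma


def test_cjs_loglik_simple_cases():
    T = 3
    empty = _marray_single(T, {}, 0)
    rates = _const_rates(T, phi_ad=0.5)
    p = np.full((4, T), 0.8)
    p[:, 0] = 0.0
    assert cjs_loglik(empty, rates, p) == 0.0
    one = _marray_single(T, {0: 1}, 0)  # released at 0, seen at 1
    assert cjs_loglik(one, rates, p) == pytest.approx(np.log(0.5 * 0.8))


def test_productivity_loglik():
    rho = np.array([2.0, 2.0, 2.0])
    assert productivity_loglik(np.array([0.0, np.nan, np.nan]),
                               np.array([0.0, np.nan, np.nan]),
                               np.array([0.0, 2.0, 2.0])) == 0.0
    assert productivity_loglik(np.array([3.0]), np.array([0.0]), np.array([2.0])) == -np.inf
    got = productivity_loglik(np.array([20.0]), np.array([10.0]), np.array([2.0]))
    assert got == pytest.approx(stats.poisson.logpmf(20, 20))


def _neutral_params(T):
    vr = VitalRateParams(
        mu=np.array([-1.0, -1.0, 0.0, 0.0, 1.0, 1.5, 1.5]),
        eps=np.zeros((T, 7)), Sigma=np.eye(7) * 0.1, beta={},
    )
    rp = RecaptureParams(mu_p=np.full(4, 2.0), eps_p=np.zeros((T, 4)),
                         sigma_p=np.full(4, 0.5))
    return vr, rp, ObservationParams(sigma_obs=0.1)


def test_prior_logdensity_support_and_neutral_point():
    T = 5
    vr, rp, op = _neutral_params(T)
    cfg = ModelConfig()
    assert np.isfinite(prior_logdensity(vr, rp, op, cfg))
    assert prior_logdensity(vr, rp, ObservationParams(sigma_obs=50.0), cfg) == -np.inf
    rp_bad = RecaptureParams(mu_p=rp.mu_p, eps_p=rp.eps_p, sigma_p=np.full(4, -1.0))
    assert prior_logdensity(vr, rp_bad, op, cfg) == -np.inf


def test_prior_survival_mean_is_uniform_on_probability_scale():
    """Sampling the logistic prior and inverting the link must give a mean
    survival of 1/2 (uniform on the probability scale)."""
    rng = np.random.default_rng(4)
    draws = rng.logistic(size=200_000)
    assert expit(draws).mean() == pytest.approx(0.5, abs=0.005)


def _toy_data_and_state(seed=0):
    from fullcycle.model import build_ipm_data
    from fullcycle.synthetic import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_years=8, gap_years=frozenset({4}), seed=seed, beta={})
    truth, enc, counts, prod = simulate_dataset(cfg)
    data = build_ipm_data(enc, counts, prod, truth.covariates, cfg.gap_years)
    T = data.n_years
    vr, rp, op = _neutral_params(T)
    lat = LatentStates(R=truth.R, S=truth.S, I=truth.I, F_tot=truth.F_tot, F_f=truth.F_f)
    return vr, rp, op, lat, data


def test_joint_posterior_additivity_and_block_oracle():
    vr, rp, op, lat, data = _toy_data_and_state()
    parts = joint_log_posterior(vr, rp, op, lat, data)
    assert parts["total"] == pytest.approx(
        parts["state"] + parts["obs"] + parts["cjs"] + parts["productivity"] + parts["prior"]
    )
    # dropping the productivity data changes the total by exactly that block
    data2 = IPMData(
        marr=data.marr, counts=data.counts, J=np.full_like(data.J, np.nan),
        females_surveyed=data.females_surveyed, X=data.X,
        cov_names=data.cov_names, gap_years=data.gap_years,
    )
    parts2 = joint_log_posterior(vr, rp, op, lat, data2)
    assert parts2["total"] == pytest.approx(parts["total"] - parts["productivity"])


def test_joint_posterior_neg_inf_propagates_without_exception():
    vr, rp, op, lat, data = _toy_data_and_state()
    lat_bad = LatentStates(
        R=lat.R.copy(), S=lat.S.copy(), I=lat.I.copy(),
        F_tot=lat.F_tot.copy(), F_f=lat.F_f.copy(),
    )
    lat_bad.R[0, 1] = lat_bad.F_f[0] + 50  # impossible recruitment
    parts = joint_log_posterior(vr, rp, op, lat_bad, data)
    assert parts["state"] == -np.inf and parts["total"] == -np.inf
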
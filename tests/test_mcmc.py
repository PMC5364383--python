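"""Sampler correctness: bookkeeping, reproducibility, a conjugate sub-model
grid oracle, convergence diagnostics and derived series."""

import numpy as np
import pytest

from fullcycle.constants import GROUPS
from fullcycle.io import MArraySet
from fullcycle.model import IPMData, ModelConfig
from fullcycle.mcmc import (
    McmcConfig,
    Posterior,
    _psrf,
    derive_lambda,
    derive_omega,
    gelman_rubin,
    log_trend_slope,
    posterior_series_correlation,
    run_mcmc,
)


def test_mcmc_config_bookkeeping_formula():
    assert McmcConfig().n_retained == 15_000  # study schedule
    cfg = McmcConfig(n_chains=2, n_iter=730, n_burnin=300, thin=7)
    assert cfg.n_retained_per_chain == 61
    with pytest.raises(ValueError):
        McmcConfig(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError):
        McmcConfig(thin=0)


def test_run_mcmc_bookkeeping_and_determinism(small_dataset):
    *_, data = small_dataset
    cfg = McmcConfig(n_chains=2, n_iter=700, n_burnin=300, thin=7, seed=5)
    post = run_mcmc(data, ModelConfig(), cfg)
    assert post.draws["mu"].shape[:2] == (2, (700 - 300) // 7)
    post2 = run_mcmc(data, ModelConfig(), cfg)
    for k in post.draws:
        assert np.array_equal(post.draws[k], post2.draws[k])
    # latent accounting identity holds in every draw
    assert (post.B == post.draws["R"] + post.draws["S"] + post.draws["I"]).all()


def _productivity_only_data(T=10, seed=3):
    rng = np.random.default_rng(seed)
    ma = MArraySet(n_occasions=T)
    for g in GROUPS:
        ma.m[g] = np.zeros((T - 1, T), dtype=np.int64)
        ma.releases[g] = np.zeros(T - 1, dtype=np.int64)
    females = np.full(T, 40.0)
    rho_true = 2.5
    J = rng.poisson(rho_true * females).astype(float)
    data = IPMData(
        marr=ma, counts=np.full((2, T), np.nan), J=J, females_surveyed=females,
        X=np.zeros((T, 1)), cov_names=["null"], gap_years=frozenset(),
    )
    return data, J, females


def test_fecundity_posterior_matches_grid_oracle():
    """With latents and residuals fixed and only productivity data, the
    posterior of the fecundity mean must match 1-D grid integration."""
    from scipy.special import gammaln

    T = 10
    data, J, females = _productivity_only_data(T)
    R = np.full((2, T), 5, dtype=np.int64)
    S = np.full((2, T), 10, dtype=np.int64)
    I = np.full((2, T), 5, dtype=np.int64)
    Ftot = np.full(T, 40, dtype=np.int64)
    Ff = np.full(T, 20, dtype=np.int64)
    post = run_mcmc(
        data, ModelConfig(), McmcConfig(n_chains=2, n_iter=20_000, n_burnin=5_000, thin=5, seed=7),
        latents_fixed=True, eps_fixed=True, init_latents=(R, S, I, Ftot, Ff),
    )
    draws = post.stack("mu")[:, 4]

    grid = np.linspace(0.3, 1.6, 4001)
    ll = np.zeros_like(grid)
    B_f = R[0] + S[0] + I[0]
    for t in range(T):
        lam1 = np.exp(grid) * females[t]
        ll += J[t] * np.log(lam1) - lam1 - gammaln(J[t] + 1)
        lam2 = np.exp(grid) * B_f[t]
        ll += Ftot[t] * np.log(lam2) - lam2 - gammaln(Ftot[t] + 1)
    ll += -0.5 * (grid / 10.0) ** 2  # prior on the log-scale mean
    w = np.exp(ll - ll.max())
    w /= w.sum()
    grid_mean = float((grid * w).sum())
    grid_sd = float(np.sqrt(((grid - grid_mean) ** 2 * w).sum()))
    mcse = grid_sd / np.sqrt(200)  # generous effective-sample allowance
    assert draws.mean() == pytest.approx(grid_mean, abs=4 * mcse)
    assert draws.std() == pytest.approx(grid_sd, rel=0.25)


def test_psrf_behaviour(rng):
    iid = rng.standard_normal((3, 5000))
    assert _psrf(iid) == pytest.approx(1.0, abs=0.01)
    apart = np.stack([rng.standard_normal(500), 10 + rng.standard_normal(500)])
    assert _psrf(apart) > 1.1
    with pytest.warns(UserWarning):
        assert _psrf(np.zeros((2, 100))) == 1.0


def test_gelman_rubin_requires_two_chains(small_fit):
    df = gelman_rubin(small_fit)
    assert {"parameter", "rhat", "converged"} <= set(df.columns)
    assert (df["rhat"] > 0.8).all()
    single = Posterior(draws={k: v[:1] for k, v in small_fit.draws.items()})
    with pytest.raises(ValueError):
        gelman_rubin(single)


def _dummy_posterior(R, S, I, gap=frozenset()):
    T = R.shape[-1]
    data = IPMData(
        marr=None, counts=np.full((2, T), np.nan), J=np.full(T, np.nan),
        females_surveyed=np.full(T, np.nan), X=np.zeros((T, 1)),
        cov_names=["null"], gap_years=gap,
    )
    draws = {"R": R, "S": S, "I": I}
    return Posterior(draws=draws, data=data)


def test_derive_lambda_and_omega_trivial_cases():
    # one draw, one chain: B = (50,50) -> (55,45) -> lambda = 1.0
    R = np.zeros((1, 1, 2, 3), dtype=int)
    S = np.array([[[[50, 55, 60], [50, 45, 60]]]])
    I = np.zeros_like(R)
    post = _dummy_posterior(R, S, I)
    lam, gap_affected = derive_lambda(post)
    assert lam[0] == pytest.approx([1.0, 1.2])
    assert not gap_affected.any()

    I2 = np.array([[[[0, 5, 0], [0, 5, 0]]]])
    S2 = np.array([[[[50, 50, 50], [50, 40, 50]]]])
    post2 = _dummy_posterior(np.zeros_like(I2), S2, I2)
    omega = derive_omega(post2)
    assert omega[0, 0] == pytest.approx(0.1)
    post3 = _dummy_posterior(np.zeros_like(I2), S2, np.zeros_like(I2))
    assert derive_omega(post3)[0] == pytest.approx([0.0, 0.0])


def test_derive_omega_matches_truth_arithmetic(study_fit):
    omega = derive_omega(study_fit)
    I = study_fit.stack("I").sum(axis=1)
    B = study_fit.B.reshape(omega.shape[0], 2, -1).sum(axis=1)
    assert np.allclose(omega, I[:, 1:] / B[:, :-1])


def test_lambda_flags_gap_transitions(study_fit):
    lam, gap_affected = derive_lambda(study_fit)
    gap = study_fit.data.gap_years
    for t in np.flatnonzero(gap_affected):
        assert (t in gap) or (t + 1 in gap)
    assert gap_affected.sum() == len(gap) + 1


def test_posterior_series_correlation():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((50, 10))
    res = posterior_series_correlation(a, a)
    assert res["mean"] == pytest.approx(1.0)
    res = posterior_series_correlation(a, -a)
    assert res["mean"] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        posterior_series_correlation(a[:, :2], a[:, :2])
    # independent white noise: the CI spans 0 in most replicates
    hits = 0
    for rep in range(20):
        x = rng.standard_normal((30, 24))
        y = rng.standard_normal((30, 24))
        r = posterior_series_correlation(x, y)
        hits += r["ci_lo"] <= 0.0 <= r["ci_hi"]
    assert hits >= 17


def test_log_trend_slope():
    T = 10
    S = np.round(1000 * 1.01 ** np.arange(T)).astype(int)
    post = _dummy_posterior(
        np.zeros((1, 1, 2, T), dtype=int),
        np.stack([S, S])[None, None], np.zeros((1, 1, 2, T), dtype=int),
    )
    res = log_trend_slope(post)
    assert res["mean"] == pytest.approx(np.log(1.01), abs=2e-4)
    flat = _dummy_posterior(
        np.zeros((1, 1, 2, 3), dtype=int),
        np.full((1, 1, 2, 3), 40), np.zeros((1, 1, 2, 3), dtype=int),
    )
    assert log_trend_slope(flat)["mean"] == pytest.approx(0.0, abs=1e-12)
    y = np.array([[10, 30, 20], [10, 30, 20]])
    post3 = _dummy_posterior(np.zeros((1, 1, 2, 3), dtype=int), y[None, None],
                             np.zeros((1, 1, 2, 3), dtype=int))
    t = np.arange(3.0)
    beta = np.polyfit(t, np.log(2 * y[0]), 1)[0]
    assert log_trend_slope(post3)["mean"] == pytest.approx(beta)
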
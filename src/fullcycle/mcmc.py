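"""Posterior sampling and derived quantities.

``run_mcmc`` drives the compiled Metropolis-within-Gibbs core over several
chains and packs the retained draws into a :class:`Posterior`.  Derived
series (annual growth rate lambda_t, combined-sex immigration rate omega_t),
posterior correlations between annual series, and the log-abundance trend
slope are computed per draw so their uncertainty propagates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _sampler
from .model import IPMData, ModelConfig

__all__ = [
    "McmcConfig",
    "Posterior",
    "run_mcmc",
    "gelman_rubin",
    "derive_lambda",
    "derive_omega",
    "posterior_series_correlation",
    "log_trend_slope",
]


@dataclass
class McmcConfig:
    """Chain schedule.  The study-scale schedule (3 x 1,000,000 iterations,
    500,000 burn-in, thin 100 -> 15,000 retained draws) is the default; tests
    and screening fits use reduced budgets."""

    n_chains: int = 3
    n_iter: int = 1_000_000
    n_burnin: int = 500_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_retained_per_chain


def reduced_budget(seed: int = 0, n_chains: int = 3) -> McmcConfig:
    """The reduced test budget: 3 x 20,000 iterations, burn-in 10,000, thin 10."""
    return McmcConfig(n_chains=n_chains, n_iter=20_000, n_burnin=10_000, thin=10, seed=seed)


@dataclass
class Posterior:
    """Retained draws with chain/draw indexing.

    Scalar blocks have shape (chains, draws_per_chain, ...); ``stack(name)``
    returns the chain-flattened view.  Latent-state draws satisfy
    B = R + S + I by construction.
    """

    draws: dict = dc_field(default_factory=dict)
    data: IPMData | None = None
    config: ModelConfig | None = None
    mcmc: McmcConfig | None = None
    acceptance: dict = dc_field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        a = next(iter(self.draws.values()))
        return a.shape[0] * a.shape[1]

    def stack(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def B(self) -> np.ndarray:
        return self.draws["R"] + self.draws["S"] + self.draws["I"]

    def scalar_table(self) -> pd.DataFrame:
        """Flat per-draw table of scalar parameters, named block[index]."""
        cols = {}
        for name in ("mu", "beta", "mu_p", "sigma_p"):
            if name not in self.draws or self.draws[name].shape[-1] == 0:
                continue
            a = self.stack(name)
            for j in range(a.shape[1]):
                cols[f"{name}[{j}]"] = a[:, j]
        cols["sigma_obs"] = self.stack("sigma_obs")
        S = self.stack("Sigma")
        for j in range(7):
            cols[f"Sigma[{j},{j}]"] = S[:, j, j]
        return pd.DataFrame(cols)


def _initial_latents(data: IPMData, rng: np.random.Generator):
    """Initialize stage abundances from the observed counts (gaps interpolated),
    split by plausible stage proportions and clipped into the model support."""
    T = data.n_years
    C = data.counts.copy()
    for s in range(2):
        series = pd.Series(C[s]).interpolate(limit_direction="both")
        C[s] = series.to_numpy()
    B0 = np.maximum(np.round(C), 2).astype(np.int64)
    R = np.round(0.3 * B0).astype(np.int64)
    S = np.round(0.5 * B0).astype(np.int64)
    I = B0 - R - S
    rho0 = 3.0
    Ftot = np.round(rho0 * B0[0]).astype(np.int64)
    Ff = Ftot // 2
    # enforce supports: R_{t+1} <= F_sex_t, S_{t+1} <= B_t
    for t in range(T - 1):
        Fsex = np.array([Ff[t], Ftot[t] - Ff[t]])
        for s in range(2):
            if R[s, t + 1] > Fsex[s]:
                d = R[s, t + 1] - Fsex[s]
                R[s, t + 1] -= d
                I[s, t + 1] += d
            if S[s, t + 1] > B0[s, t]:
                d = S[s, t + 1] - B0[s, t]
                S[s, t + 1] -= d
                I[s, t + 1] += d
    return R, S, I, Ftot, Ff


def _pack_data(data: IPMData):
    from .constants import GROUPS

    T = data.n_years
    marr = np.stack([data.marr.m[g] for g in GROUPS]).astype(np.int64)
    rel = np.stack([data.marr.releases[g] for g in GROUPS]).astype(np.int64)
    obs_mask = np.isfinite(data.counts) & (data.counts > 0)
    logC = np.where(obs_mask, np.log(np.where(obs_mask, data.counts, 1.0)), 0.0)
    prod_mask = (np.isfinite(data.J) & np.isfinite(data.females_surveyed)).astype(np.uint8)
    J = np.where(prod_mask == 1, data.J, 0.0)
    Cf = np.where(prod_mask == 1, data.females_surveyed, 0.0)
    det_mask = data.detection_occasions().astype(np.uint8)
    X = np.asarray(data.X, dtype=np.float64)
    if X.size == 0:
        X = np.zeros((T, 1))
    return marr, rel, logC, obs_mask.astype(np.uint8), J, Cf, prod_mask, X, det_mask


def run_mcmc(
    data: IPMData,
    model_config: ModelConfig | None = None,
    mcmc_config: McmcConfig | None = None,
    latents_fixed: bool = False,
    eps_fixed: bool = False,
    init_latents: tuple | None = None,
) -> Posterior:
    """Sample the joint posterior of the integrated population model.

    Chains start from jittered prior medians (parameters) and count-derived
    stage splits (latents); each chain's seed is spawned deterministically
    from ``mcmc_config.seed``.
    """
    model_config = ModelConfig() if model_config is None else model_config
    mcmc_config = McmcConfig() if mcmc_config is None else mcmc_config
    T = data.n_years
    brate, bcov = model_config.design_arrays(data.cov_names)
    nb = len(brate)
    marr, rel, logC, obs_mask, J, Cf, prod_mask, X, det_mask = _pack_data(data)

    n_keep = mcmc_config.n_retained_per_chain
    nc = mcmc_config.n_chains
    out = {
        "mu": np.zeros((nc, n_keep, 7)),
        "beta": np.zeros((nc, n_keep, nb)),
        "mu_p": np.zeros((nc, n_keep, 4)),
        "sigma_p": np.zeros((nc, n_keep, 4)),
        "sigma_obs": np.zeros((nc, n_keep)),
        "Sigma": np.zeros((nc, n_keep, 7, 7)),
        "phi_j": np.zeros((nc, n_keep, 2, T - 1)),
        "phi_ad": np.zeros((nc, n_keep, 2, T - 1)),
        "rho": np.zeros((nc, n_keep, T)),
        "iota": np.zeros((nc, n_keep, 2, T)),
        "p": np.zeros((nc, n_keep, 4, T)),
        "R": np.zeros((nc, n_keep, 2, T), dtype=np.int64),
        "S": np.zeros((nc, n_keep, 2, T), dtype=np.int64),
        "I": np.zeros((nc, n_keep, 2, T), dtype=np.int64),
        "F_tot": np.zeros((nc, n_keep, T), dtype=np.int64),
        "F_f": np.zeros((nc, n_keep, T), dtype=np.int64),
    }

    ss = np.random.SeedSequence(mcmc_config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(nc)]
    for c in range(nc):
        rng = np.random.default_rng(chain_seeds[c])
        # jittered prior-median initial values
        mu = np.concatenate([rng.normal(0, 0.3, 4), np.array([np.log(3.0), np.log(5.0), np.log(5.0)]) + rng.normal(0, 0.2, 3)])
        beta = rng.normal(0, 0.1, nb)
        eps = np.zeros((T, 7)) if eps_fixed else rng.normal(0, 0.05, (T, 7))
        Sigma0 = np.eye(7) * 0.1
        mu_p = rng.normal(2.0, 0.3, 4)
        eps_p = np.zeros((T, 4))
        sigma_p = np.full(4, 0.5)
        sigma_obs = 0.1
        if init_latents is not None:
            R, S, I, Ftot, Ff = (a.copy() for a in init_latents)
        else:
            R, S, I, Ftot, Ff = _initial_latents(data, rng)

        got = _sampler.run_chain(
            chain_seeds[c], mcmc_config.n_iter, mcmc_config.n_burnin, mcmc_config.thin,
            marr, rel, logC, obs_mask, J, Cf, prod_mask, X, det_mask,
            brate, bcov,
            mu, beta, eps, Sigma0, mu_p, eps_p, sigma_p, sigma_obs,
            R, S, I, Ftot, Ff,
            model_config.sigma_prior == "diag-halfnormal", latents_fixed, eps_fixed,
            out["mu"][c], out["beta"][c], out["mu_p"][c], out["sigma_p"][c],
            out["sigma_obs"][c], out["Sigma"][c],
            out["phi_j"][c], out["phi_ad"][c], out["rho"][c], out["iota"][c], out["p"][c],
            out["R"][c], out["S"][c], out["I"][c], out["F_tot"][c], out["F_f"][c],
        )
        if got != n_keep:  # pragma: no cover - defensive
            raise RuntimeError(f"chain {c} retained {got} draws, expected {n_keep}")

    return Posterior(draws=out, data=data, config=model_config, mcmc=mcmc_config)


# ---------------------------------------------------------------------------
# convergence


def gelman_rubin(posterior: Posterior, threshold: float = 1.005) -> pd.DataFrame:
    """Classic potential-scale-reduction statistic per scalar parameter.

    Chains with zero between- and within-variance (constant) report 1 by
    convention, with a warning.  Requires >= 2 chains.
    """
    if posterior.n_chains < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    rows = []
    for name in ("mu", "beta", "mu_p", "sigma_p"):
        a = posterior.draws.get(name)
        if a is None or a.shape[-1] == 0:
            continue
        for j in range(a.shape[2]):
            rows.append((f"{name}[{j}]", _psrf(a[:, :, j])))
    rows.append(("sigma_obs", _psrf(posterior.draws["sigma_obs"])))
    df = pd.DataFrame(rows, columns=["parameter", "rhat"])
    df["converged"] = df["rhat"] < threshold
    return df


def _psrf(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    Bv = n * means.var(ddof=1)
    if W == 0:
        if Bv == 0:
            warnings.warn("constant chains: R-hat reported as 1 by convention")
            return 1.0
        return np.inf
    var_plus = (n - 1) / n * W + Bv / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# derived series


def derive_lambda(posterior: Posterior) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw growth rate lambda_t = B_{t+1}/B_t (sexes combined).

    Returns (lam, gap_affected): lam has shape (n_draws, T-1); gap_affected
    flags transitions that start or end in a monitoring-gap year.  Zero
    denominators yield NaN with a warning.
    """
    B = posterior.B.reshape(-1, 2, posterior.data.n_years).sum(axis=1).astype(float)
    denom = B[:, :-1]
    if (denom == 0).any():
        warnings.warn("zero breeder total: lambda undefined for some transitions")
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(denom > 0, B[:, 1:] / denom, np.nan)
    gap = posterior.data.gap_years
    T = posterior.data.n_years
    gap_affected = np.array([(t in gap) or ((t + 1) in gap) for t in range(T - 1)])
    return lam, gap_affected


def derive_omega(posterior: Posterior) -> np.ndarray:
    """Per-draw combined-sex immigration rate
    omega_t = (I_{f,t+1} + I_{m,t+1}) / (B_{f,t} + B_{m,t})."""
    T = posterior.data.n_years
    I = posterior.stack("I").sum(axis=1).astype(float)
    B = posterior.B.reshape(-1, 2, T).sum(axis=1).astype(float)
    denom = B[:, :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, I[:, 1:] / denom, np.nan)


def posterior_series_correlation(a: np.ndarray, b: np.ndarray) -> dict:
    """Posterior of the Pearson correlation across years of two per-draw
    series (n_draws, T); summarized as mean and equal-tail 95% CI."""
    ok = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 common non-missing years")
    aa, bb = a[:, ok], b[:, ok]
    az = aa - aa.mean(axis=1, keepdims=True)
    bz = bb - bb.mean(axis=1, keepdims=True)
    num = (az * bz).sum(axis=1)
    den = np.sqrt((az**2).sum(axis=1) * (bz**2).sum(axis=1))
    r = num / den
    return {
        "draws": r,
        "mean": float(r.mean()),
        "ci_lo": float(np.quantile(r, 0.025)),
        "ci_hi": float(np.quantile(r, 0.975)),
    }


def log_trend_slope(posterior: Posterior) -> dict:
    """Per-draw OLS slope of log total breeders on year; mean and 95% CI."""
    T = posterior.data.n_years
    B = posterior.B.reshape(-1, 2, T).sum(axis=1).astype(float)
    t = np.arange(T, dtype=float)
    tz = t - t.mean()
    logB = np.log(B)
    slope = (logB * tz).sum(axis=1) / (tz**2).sum()
    return {
        "draws": slope,
        "mean": float(slope.mean()),
        "ci_lo": float(np.quantile(slope, 0.025)),
        "ci_hi": float(np.quantile(slope, 0.975)),
    }
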
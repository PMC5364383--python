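"""Weather and density covariate screening for the vital rates.

Each candidate covariate is screened by refitting the full integrated model
with a single slope coefficient active on a single vital rate, then ranking
candidates by how little the 90% credible interval of the slope overlaps 0
(operationalized as two-sided tail mass 2*min(P(beta>0), P(beta<0))).  One
winner is kept per vital rate from the breeding-ground weather set and one
from the wintering-ground set; any candidate whose 90% CI excludes 0 is
carried forward regardless.  Density covariates always enter the final
model (breeding density for every rate, de-trended for fecundity; winter
density for every rate except immigration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import BREEDING_WEATHER, RATES, WINTER_WEATHER
from .mcmc import McmcConfig, run_mcmc
from .model import IPMData, ModelConfig, with_interaction

__all__ = ["fit_univariate", "select_covariates", "fit_interaction", "screen_all"]


def _screen_covariate(vital_rate: str, covariate: str) -> str:
    # fecundity is regressed on de-trended breeding density to avoid spurious
    # density dependence from the shared long-term trend
    if vital_rate == "rho" and covariate == "breeding_density":
        return "breeding_density_detrended"
    return covariate


def fit_univariate(
    vital_rate: str,
    covariate: str,
    data: IPMData,
    mcmc_config: McmcConfig | None = None,
) -> dict:
    """Full IPM refit with exactly one active slope; returns its posterior."""
    if vital_rate not in RATES:
        raise ValueError(f"unknown vital rate {vital_rate!r}")
    covariate = _screen_covariate(vital_rate, covariate)
    if covariate not in data.cov_names:
        raise ValueError(f"unknown covariate {covariate!r}")
    mcmc_config = McmcConfig(n_chains=2, n_iter=6000, n_burnin=3000, thin=3) if mcmc_config is None else mcmc_config
    config = ModelConfig(beta_design=[(vital_rate, covariate)])
    post = run_mcmc(data, config, mcmc_config)
    draws = post.stack("beta")[:, 0]
    return summarize_beta(vital_rate, covariate, draws)


def summarize_beta(vital_rate: str, covariate: str, draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.05, 0.95])
    p_pos = float(np.mean(draws > 0))
    tail = 2.0 * min(p_pos, 1.0 - p_pos)
    return {
        "vital_rate": vital_rate,
        "covariate": covariate,
        "draws": draws,
        "posterior_mean": float(draws.mean()),
        "ci90_lo": float(lo),
        "ci90_hi": float(hi),
        "tail_mass": tail,
        "excludes_zero": bool(lo > 0 or hi < 0),
    }


def select_covariates(results: list[dict]) -> pd.DataFrame:
    """Apply the minimum-tail-mass rule per vital rate and candidate group.

    Ties in tail mass break to the larger |posterior mean|, then to candidate
    order.  Returns the full table with a ``selected`` flag.
    """
    if not results:
        raise ValueError("no screening results supplied")
    df = pd.DataFrame([{k: v for k, v in r.items() if k != "draws"} for r in results])
    df["selected"] = False
    for rate in df["vital_rate"].unique():
        sub = df[df["vital_rate"] == rate]
        for group in (BREEDING_WEATHER, WINTER_WEATHER):
            cand = sub[sub["covariate"].isin(group)]
            if cand.empty:
                continue
            ranked = cand.sort_values(
                by=["tail_mass", "posterior_mean"],
                key=lambda s: s.abs() if s.name == "posterior_mean" else s,
                ascending=[True, False],
                kind="stable",
            )
            df.loc[ranked.index[0], "selected"] = True
            df.loc[cand.index[cand["excludes_zero"]], "selected"] = True
    return df


def screen_all(
    data: IPMData,
    mcmc_config: McmcConfig | None = None,
    rates: tuple = RATES,
    candidates: tuple = BREEDING_WEATHER + WINTER_WEATHER,
) -> pd.DataFrame:
    """Screen every (vital rate, candidate) pair and apply the selection rule."""
    results = []
    for rate in rates:
        for cov in candidates:
            results.append(fit_univariate(rate, cov, data, mcmc_config))
    return select_covariates(results)


def fit_interaction(
    data: IPMData,
    mcmc_config: McmcConfig | None = None,
    density: str = "breeding_density",
    weather: str = "winter_temp",
) -> dict[str, dict]:
    """Breeding-density x winter-temperature interaction on annual survival.

    All four age-sex survival rates are refit together with both main effects
    and the product term (product of standardized covariates, not itself
    re-standardized); returns the interaction posterior per survival rate.
    """
    aug = with_interaction(data, density, weather)
    product = f"{density}:{weather}"
    design = []
    for rate in RATES[:4]:
        design += [(rate, density), (rate, weather), (rate, product)]
    config = ModelConfig(beta_design=design)
    mcmc_config = McmcConfig(n_chains=2, n_iter=6000, n_burnin=3000, thin=3) if mcmc_config is None else mcmc_config
    post = run_mcmc(aug, config, mcmc_config)
    beta = post.stack("beta")
    out = {}
    for j, rate in enumerate(RATES[:4]):
        draws = beta[:, 3 * j + 2]
        lo, hi = np.quantile(draws, [0.025, 0.975])
        out[rate] = {
            "draws": draws,
            "mean": float(draws.mean()),
            "ci95_lo": float(lo),
            "ci95_hi": float(hi),
        }
    return out
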
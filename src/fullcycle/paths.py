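"""Posterior-propagating path analysis of population growth rate.

For every retained posterior draw, seven normal linear models are fit on
within-draw standardized annual series: one relating growth rate lambda_t to
the six vital rates (four age-sex survivals, fecundity, combined-sex
immigration rate omega), and six relating each vital rate to its weather and
density covariates.  The indirect effect of covariate X on lambda via vital
rate V is the product of the two standardized coefficients; summing over
vital rates gives X's cumulative indirect effect.  Fitting per draw
propagates the full posterior uncertainty of the vital rates into the effect
estimates.

Years affected by the monitoring gap (a transition starting or ending in a
gap year) are removed listwise before standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .mcmc import Posterior, derive_lambda, derive_omega

__all__ = [
    "PathInputs",
    "default_roster",
    "assemble_path_inputs",
    "fit_path_models",
    "fit_all_path_models",
    "indirect_effects",
    "summarize_effects",
    "run_path_analysis",
]

VITAL_ORDER = ("phi_j_f", "phi_j_m", "phi_ad_f", "phi_ad_m", "rho", "omega")


def default_roster(selection: pd.DataFrame | None = None) -> dict[str, list[str]]:
    """Covariate roster per vital-rate sub-model.

    With a selection table, each rate's winners are used; otherwise winter
    temperature and breeding-season temperature stand in.  Breeding density
    enters every sub-model (de-trended for fecundity); winter density enters
    all but the immigration sub-model.
    """
    winners: dict[str, list[str]] = {}
    if selection is not None:
        sel = selection[selection["selected"]]
        for rate in sel["vital_rate"].unique():
            winners[rate] = list(sel.loc[sel["vital_rate"] == rate, "covariate"])
        winners["omega"] = sorted(
            set(winners.get("iota_f", ["winter_temp"])) | set(winners.get("iota_m", ["winter_temp"]))
        )
    roster = {}
    for rate in VITAL_ORDER:
        weather = winners.get(rate, ["winter_temp", "breeding_temp"])
        if rate == "rho":
            dens = ["breeding_density_detrended", "winter_density"]
        elif rate == "omega":
            dens = ["breeding_density"]  # winter density excluded for immigration
        else:
            dens = ["breeding_density", "winter_density"]
        roster[rate] = list(dict.fromkeys(weather + dens))
    return roster


@dataclass
class PathInputs:
    """Within-draw standardized series over the usable (non-gap) transition
    years: ``series[name]`` has shape (n_draws, n_years_used)."""

    series: dict = dc_field(default_factory=dict)
    covariates: dict = dc_field(default_factory=dict)
    years: np.ndarray = None
    roster: dict = dc_field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.series.values())).shape[0]


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    mean = a.mean(axis=-1, keepdims=True)
    sd = a.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant series")
    return (a - mean) / sd


def assemble_path_inputs(
    posterior: Posterior, roster: dict[str, list[str]] | None = None, min_years: int = 5
) -> PathInputs:
    """Align lambda, the vital rates and the covariates on transition years,
    drop gap-affected years listwise, and standardize within each draw."""
    data = posterior.data
    T = data.n_years
    roster = default_roster() if roster is None else roster
    lam, gap_affected = derive_lambda(posterior)
    omega = derive_omega(posterior)
    usable = ~gap_affected
    years = np.flatnonzero(usable)
    if len(years) < min_years:
        raise ValueError(f"only {len(years)} usable years; need >= {min_years}")

    series = {
        "lam": _standardize_rows(lam[:, years]),
        "omega": _standardize_rows(omega[:, years]),
        "rho": _standardize_rows(posterior.stack("rho")[:, years]),
    }
    phi_j = posterior.stack("phi_j")
    phi_ad = posterior.stack("phi_ad")
    for s, lab in enumerate("fm"):
        series[f"phi_j_{lab}"] = _standardize_rows(phi_j[:, s, years])
        series[f"phi_ad_{lab}"] = _standardize_rows(phi_ad[:, s, years])

    needed = sorted({c for covs in roster.values() for c in covs})
    covariates = {}
    for c in needed:
        x = data.X[:, data.cov_names.index(c)][years]
        covariates[c] = _standardize_rows(x[None, :])[0]
    return PathInputs(series=series, covariates=covariates, years=years, roster=roster)


def _batched_ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    """OLS coefficients per draw: X (D, n, k), y (D, n) -> (D, k)."""
    if np.linalg.matrix_rank(X[0]) < X.shape[2]:
        raise ValueError(f"rank-deficient design; columns: {names}")
    G = np.einsum("dni,dnj->dij", X, X)
    c = np.einsum("dni,dn->di", X, y)
    return np.linalg.solve(G, c[:, :, None])[:, :, 0]


def fit_all_path_models(inputs: PathInputs) -> dict:
    """All seven sub-models for every draw.

    Returns ``{"lambda": (D, 6) coefficients in VITAL_ORDER,
    "<rate>": (D, k_rate) coefficients in roster order}``.
    """
    D = inputs.n_draws
    Xl = np.stack([inputs.series[v] for v in VITAL_ORDER], axis=2)
    coeffs = {"lambda": _batched_ols(Xl, inputs.series["lam"], list(VITAL_ORDER))}
    for rate in VITAL_ORDER:
        covs = inputs.roster[rate]
        Xr = np.stack(
            [np.broadcast_to(inputs.covariates[c], (D, len(inputs.years))) for c in covs],
            axis=2,
        )
        coeffs[rate] = _batched_ols(Xr, inputs.series[rate], covs)
    return coeffs


def fit_path_models(inputs: PathInputs, draw: int) -> dict:
    """The seven-model coefficient set for a single draw (reference path;
    the batched fit is the fast equivalent and is tested against this)."""
    out = {}
    Xl = np.stack([inputs.series[v][draw] for v in VITAL_ORDER], axis=1)
    out["lambda"], *_ = np.linalg.lstsq(Xl, inputs.series["lam"][draw], rcond=None)
    for rate in VITAL_ORDER:
        covs = inputs.roster[rate]
        Xr = np.stack([inputs.covariates[c] for c in covs], axis=1)
        out[rate], *_ = np.linalg.lstsq(Xr, inputs.series[rate][draw], rcond=None)
    return out


def indirect_effects(coeffs: dict, roster: dict[str, list[str]]) -> dict:
    """Per-draw decomposition: indirect(X via V) = beta(X->V) * beta(V->lambda);
    cumulative(X) = sum over V.  The identity holds exactly by construction."""
    lam_coef = coeffs["lambda"]
    single = lam_coef.ndim == 1
    if single:
        lam_coef = lam_coef[None, :]
    D = lam_coef.shape[0]
    indirect: dict[tuple[str, str], np.ndarray] = {}
    cumulative: dict[str, np.ndarray] = {}
    for vi, rate in enumerate(VITAL_ORDER):
        b_rate = coeffs[rate] if not single else np.asarray(coeffs[rate])[None, :]
        for ci, cov in enumerate(roster[rate]):
            eff = b_rate[:, ci] * lam_coef[:, vi]
            indirect[(cov, rate)] = eff
            cumulative[cov] = cumulative.get(cov, np.zeros(D)) + eff
    if single:
        indirect = {k: v[0] for k, v in indirect.items()}
        cumulative = {k: v[0] for k, v in cumulative.items()}
    return {"indirect": indirect, "cumulative": cumulative}


def summarize_effects(coeffs: dict, roster: dict[str, list[str]]) -> pd.DataFrame:
    """Posterior mean and equal-tail 95% CI for every direct and cumulative
    indirect effect, as a flat effects table."""
    eff = indirect_effects(coeffs, roster)
    rows = []

    def _row(effect_type, source, target, draws):
        draws = np.asarray(draws)
        rows.append(
            {
                "effect_type": effect_type,
                "source": source,
                "target": target,
                "mean": float(draws.mean()),
                "ci_lo": float(np.quantile(draws, 0.025)),
                "ci_hi": float(np.quantile(draws, 0.975)),
                "n_draws": draws.size,
            }
        )

    for vi, rate in enumerate(VITAL_ORDER):
        _row("direct", rate, "lambda", coeffs["lambda"][:, vi])
        for ci, cov in enumerate(roster[rate]):
            _row("direct", cov, rate, coeffs[rate][:, ci])
    for (cov, rate), draws in eff["indirect"].items():
        _row("indirect", cov, f"lambda via {rate}", draws)
    for cov, draws in eff["cumulative"].items():
        _row("cumulative", cov, "lambda", draws)
    return pd.DataFrame(rows)


def run_path_analysis(
    posterior: Posterior, roster: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Assemble, fit and summarize in one call."""
    inputs = assemble_path_inputs(posterior, roster)
    coeffs = fit_all_path_models(inputs)
    return summarize_effects(coeffs, inputs.roster)
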
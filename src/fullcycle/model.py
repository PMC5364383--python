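"""Joint log-density of the integrated population model.

The model couples four likelihood blocks through shared vital rates:

* a state-space block: binomial/Poisson projection of local recruits R,
  surviving adults S and immigrants I (two sexes), with breeders
  B = R + S + I;
* a lognormal count observation block, log C ~ Normal(log B, sigma_obs);
* a Cormack-Jolly-Seber block on age/sex-specific m-arrays;
* a Poisson productivity block, J_t ~ Poisson(rho_t * females_surveyed_t).

Vital rates are built from link-scale means, covariate effects and
multivariate-normal temporal residuals: survival and detection on the logit
scale, fecundity and expected immigrants on the log scale.  All densities are
computed in log space; impossible transitions return -inf, never raise.

Indexing: residual row t carries survival for interval t -> t+1, fecundity of
year t, and the expected immigrants arriving in year t+1 — so winter-window
covariates indexed to t act on the mortality interval and the immigration
pulse they drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import gammaln, expit

from .constants import GROUPS, RATES
from .io import MArraySet

__all__ = [
    "VitalRateParams",
    "RecaptureParams",
    "ObservationParams",
    "LatentStates",
    "IPMData",
    "ModelConfig",
    "build_ipm_data",
    "with_interaction",
    "vital_rate_series",
    "state_loglik",
    "obs_loglik",
    "cjs_cell_probs",
    "cjs_loglik",
    "productivity_loglik",
    "prior_logdensity",
    "joint_log_posterior",
]

NEG_INF = -np.inf
INIT_MAX = 300  # discrete-uniform prior bound on first-year stage abundances


# ---------------------------------------------------------------------------
# Parameter and data containers


@dataclass
class VitalRateParams:
    """mu: link-scale means (7,); beta: {(rate, covariate): coefficient};
    eps: (T, 7) temporal residuals, rows ~ MVN(0, Sigma)."""

    mu: np.ndarray
    eps: np.ndarray
    Sigma: np.ndarray
    beta: dict = dc_field(default_factory=dict)


@dataclass
class RecaptureParams:
    """mu_p: logit-scale means per group (juv_f, juv_m, ad_f, ad_m);
    eps_p: (T, 4) independent normal residuals; sigma_p: their SDs."""

    mu_p: np.ndarray
    eps_p: np.ndarray
    sigma_p: np.ndarray


@dataclass
class ObservationParams:
    sigma_obs: float = 0.1


@dataclass
class LatentStates:
    """Stage abundances, indexed [sex, year] (0=f, 1=m)."""

    R: np.ndarray
    S: np.ndarray
    I: np.ndarray
    F_tot: np.ndarray
    F_f: np.ndarray

    @property
    def B(self) -> np.ndarray:
        return self.R + self.S + self.I

    @property
    def F_sex(self) -> np.ndarray:
        return np.stack([self.F_f, self.F_tot - self.F_f])


@dataclass
class IPMData:
    """Observed data plus the standardized covariate matrix X (T, n_cov)."""

    marr: MArraySet
    counts: np.ndarray  # (2, T), NaN = missing
    J: np.ndarray  # (T,), NaN = missing
    females_surveyed: np.ndarray  # (T,)
    X: np.ndarray  # (T, n_cov) standardized covariates
    cov_names: list
    gap_years: frozenset

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]

    def detection_occasions(self) -> np.ndarray:
        T = self.n_years
        mask = np.zeros(T, dtype=bool)
        mask[1:] = True
        mask[list(self.gap_years)] = False
        return mask


def build_ipm_data(
    enc,
    counts: "pd.DataFrame",
    productivity: "pd.DataFrame",
    covariates: "pd.DataFrame",
    gap_years,
) -> "IPMData":
    """Assemble the model's data block from the four observed tables.

    Covariates are standardized (population SD); the breeding-density
    covariate is the observed peak count C_f + C_m, also provided de-trended
    (fecundity's density covariate).  Standardized values in unmonitored gap
    years are imputed at the mean (0), which is neutral for the link-scale
    regressions.
    """
    import pandas as pd

    from .io import build_marray, detrend_series, zscore

    marr = build_marray(enc)
    T = marr.n_occasions
    counts_arr = np.stack(
        [counts["C_f"].to_numpy(dtype=float), counts["C_m"].to_numpy(dtype=float)]
    )
    density = counts_arr.sum(axis=0)
    cols: dict[str, np.ndarray] = {}
    for name in covariates.columns:
        if name == "year":
            continue
        cols[name] = covariates[name].to_numpy(dtype=float)
    cols["breeding_density"] = density
    cols["breeding_density_detrended"] = detrend_series(density)
    names, Xcols = [], []
    for name, v in cols.items():
        z, _, _ = zscore(v)
        names.append(name)
        Xcols.append(np.where(np.isfinite(z), z, 0.0))
    return IPMData(
        marr=marr,
        counts=counts_arr,
        J=productivity["J"].to_numpy(dtype=float),
        females_surveyed=productivity["females_surveyed"].to_numpy(dtype=float),
        X=np.column_stack(Xcols),
        cov_names=names,
        gap_years=frozenset(gap_years),
    )


def with_interaction(data: "IPMData", cov_a: str, cov_b: str) -> "IPMData":
    """Copy of the data block with a product column ``cov_a:cov_b`` appended
    (product of the standardized covariates, itself not re-standardized)."""
    ia, ib = data.cov_names.index(cov_a), data.cov_names.index(cov_b)
    X = np.column_stack([data.X, data.X[:, ia] * data.X[:, ib]])
    return IPMData(
        marr=data.marr,
        counts=data.counts,
        J=data.J,
        females_surveyed=data.females_surveyed,
        X=X,
        cov_names=[*data.cov_names, f"{cov_a}:{cov_b}"],
        gap_years=data.gap_years,
    )


@dataclass
class ModelConfig:
    """Which covariate effects are active, and prior/structure switches."""

    beta_design: list = dc_field(default_factory=list)  # [(rate, covariate), ...]
    sigma_prior: str = "invwishart"  # or "diag-halfnormal"
    iw_df: float = 9.0
    time_varying_sigma_obs: bool = False  # one sigma by default

    def design_arrays(self, cov_names: list) -> tuple[np.ndarray, np.ndarray]:
        rate_idx = np.array([RATES.index(r) for r, _ in self.beta_design], dtype=np.int64)
        cov_idx = np.array([cov_names.index(c) for _, c in self.beta_design], dtype=np.int64)
        return rate_idx, cov_idx


# ---------------------------------------------------------------------------
# Elementary log-pmfs (support violations give -inf)


def _binom_logpmf(k, n, p):
    k, n, p = np.asarray(k), np.asarray(n), np.asarray(p, dtype=float)
    out = np.full(np.broadcast(k, n, p).shape, NEG_INF)
    ok = (k >= 0) & (k <= n) & (p >= 0) & (p <= 1)
    kk, nn, pp = np.broadcast_arrays(k, n, p)
    kk, nn, pp = kk[ok], nn[ok], pp[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(kk > 0, kk * np.log(pp), 0.0) + np.where(
            nn - kk > 0, (nn - kk) * np.log1p(-pp), 0.0
        )
    out[ok] = gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1) + term
    return out if out.shape else float(out)


def _pois_logpmf(k, lam):
    k, lam = np.asarray(k), np.asarray(lam, dtype=float)
    out = np.full(np.broadcast(k, lam).shape, NEG_INF)
    kk, ll = np.broadcast_arrays(k, lam)
    ok = (kk >= 0) & (ll >= 0) & ((ll > 0) | (kk == 0))
    kz = ok & (ll == 0)
    out[kz] = 0.0
    op = ok & (ll > 0)
    out[op] = kk[op] * np.log(ll[op]) - ll[op] - gammaln(kk[op] + 1)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Vital-rate construction


def vital_rate_series(mu, beta, X, eps, link):
    """Annual rate series from link-scale mean, covariate effects and residuals.

    ``beta`` maps covariate column index -> coefficient; ``X`` is the
    standardized covariate matrix (T, n_cov); ``link`` is 'logit' or 'log'.
    """
    eta = mu + np.asarray(eps, dtype=float)
    for j, b in beta.items():
        eta = eta + b * X[:, j]
    if link == "logit":
        return expit(eta)
    if link == "log":
        return np.exp(eta)
    raise ValueError(f"unknown link {link!r}")


def compute_rates(params: VitalRateParams, X: np.ndarray, cov_names: list) -> dict:
    """All seven natural-scale rate series from one parameter block.

    Returns phi_j, phi_ad with shape (2, T-1) for intervals t -> t+1; rho (T,);
    iota (2, T) where iota[:, t] is the expectation of arrivals in year t.
    """
    T = params.eps.shape[0]
    by_rate: dict[int, dict[int, float]] = {}
    for (r, c), b in params.beta.items():
        ri = RATES.index(r) if isinstance(r, str) else r
        ci = cov_names.index(c) if isinstance(c, str) else c
        by_rate.setdefault(ri, {})[ci] = b
    series = []
    for ri in range(7):
        link = "logit" if ri < 4 else "log"
        series.append(
            vital_rate_series(params.mu[ri], by_rate.get(ri, {}), X, params.eps[:, ri], link)
        )
    phi_j = np.stack([series[0][: T - 1], series[1][: T - 1]])
    phi_ad = np.stack([series[2][: T - 1], series[3][: T - 1]])
    rho = series[4]
    iota = np.zeros((2, T))
    iota[0, 1:] = series[5][: T - 1]
    iota[1, 1:] = series[6][: T - 1]
    return {"phi_j": phi_j, "phi_ad": phi_ad, "rho": rho, "iota": iota}


def detection_series(params: RecaptureParams, det_mask: np.ndarray) -> np.ndarray:
    """(4, T) detection probabilities; structurally zero off detection occasions."""
    T = params.eps_p.shape[0]
    p = np.zeros((4, T))
    for g in range(4):
        p[g] = expit(params.mu_p[g] + params.eps_p[:, g])
    p[:, ~det_mask] = 0.0
    return p


# ---------------------------------------------------------------------------
# Likelihood blocks


def state_loglik(latents: LatentStates, rates: dict) -> float:
    """Log-density of the binomial/Poisson projection given the rate series."""
    R, S, I = latents.R, latents.S, latents.I
    B, F_sex = latents.B, latents.F_sex
    T = R.shape[1]
    ll = 0.0
    for s in range(2):
        for x in (R[s, 0], S[s, 0], I[s, 0]):
            ll += -np.log(INIT_MAX + 1) if 0 <= x <= INIT_MAX else NEG_INF
    ll += _pois_logpmf(latents.F_tot, rates["rho"] * B[0]).sum()
    ll += _binom_logpmf(latents.F_f, latents.F_tot, 0.5).sum()
    for s in range(2):
        ll += _binom_logpmf(R[s, 1:], F_sex[s, : T - 1], rates["phi_j"][s]).sum()
        ll += _binom_logpmf(S[s, 1:], B[s, : T - 1], rates["phi_ad"][s]).sum()
        ll += _pois_logpmf(I[s, 1:], rates["iota"][s, 1:]).sum()
    return float(ll)


def obs_loglik(counts: np.ndarray, B: np.ndarray, sigma_obs: float) -> float:
    """Lognormal count likelihood; missing (gap) years contribute nothing."""
    obs = np.isfinite(counts)
    if (counts[obs] <= 0).any():
        raise ValueError("observed counts must be positive")
    if sigma_obs <= 0:
        return NEG_INF
    Bo = B[obs].astype(float)
    if (Bo <= 0).any():
        return NEG_INF
    z = (np.log(counts[obs]) - np.log(Bo)) / sigma_obs
    return float(-0.5 * np.sum(z**2) - obs.sum() * (np.log(sigma_obs) + 0.5 * np.log(2 * np.pi)))


def cjs_cell_probs(phi: np.ndarray, p: np.ndarray, release_occasion: int) -> np.ndarray:
    """Multinomial cell probabilities for one release cohort.

    ``phi[k]`` is survival over interval k -> k+1 (the caller supplies the
    age-appropriate sequence), ``p[j]`` detection at occasion j.  Returns the
    probabilities of first recapture at occasions release+1 .. T-1 followed by
    the never-seen-again cell.
    """
    T = len(p)
    i = release_occasion
    cells = np.zeros(T - i)
    chi = 1.0
    for j in range(i + 1, T):
        chi *= phi[j - 1]
        cells[j - i - 1] = chi * p[j]
        chi *= 1.0 - p[j]
    cells[-1] = 1.0 - cells[:-1].sum()
    return cells


def _group_sequences(g: int, i: int, rates: dict, p: np.ndarray, T: int):
    """Age-appropriate (phi, p) sequences for group g released at occasion i."""
    s = g % 2
    phi = rates["phi_ad"][s].astype(float).copy()
    pdet = p[2 + s].copy()
    if g < 2:  # juvenile release: first interval phi_j, detected at age 1 with juv p
        phi = phi.copy()
        phi[i] = rates["phi_j"][s, i]
        if i + 1 < T:
            pdet[i + 1] = p[s, i + 1]
    return phi, pdet


def cjs_loglik(marr: MArraySet, rates: dict, p: np.ndarray) -> float:
    """Multinomial CJS log-likelihood over all four m-arrays.

    The multinomial coefficient is omitted (constant in the parameters), which
    makes this exactly the sum of per-individual history log-probabilities.
    """
    T = marr.n_occasions
    ll = 0.0
    for gi, g in enumerate(GROUPS):
        m, rel = marr.m[g], marr.releases[g]
        for i in range(T - 1):
            if rel[i] == 0:
                continue
            phi, pdet = _group_sequences(gi, i, rates, p, T)
            cells = cjs_cell_probs(phi, pdet, i)
            row = np.concatenate([m[i, i : T - 1], [m[i, T - 1]]])
            with np.errstate(divide="ignore"):
                logc = np.log(cells)
            if np.any((row > 0) & ~np.isfinite(logc)):
                return NEG_INF
            ll += float(row @ np.where(row > 0, logc, 0.0))
    return ll


def productivity_loglik(J: np.ndarray, females_surveyed: np.ndarray, rho: np.ndarray) -> float:
    """Poisson fledgling-count likelihood; missing years are omitted."""
    obs = np.isfinite(J) & np.isfinite(females_surveyed)
    return float(_pois_logpmf(J[obs], rho[obs] * females_surveyed[obs]).sum())


# ---------------------------------------------------------------------------
# Priors and the joint density


def _logistic_logpdf(x):
    # log-density of logit(U(0,1)); vectorized, symmetric form for stability
    ax = np.abs(x)
    return -ax - 2.0 * np.log1p(np.exp(-ax))


def prior_logdensity(
    vr: VitalRateParams,
    rp: RecaptureParams,
    op: ObservationParams,
    config: ModelConfig,
    det_mask: np.ndarray | None = None,
) -> float:
    """Vague priors: survival/detection means uniform on the probability scale,
    log-scale means Normal(0, 10); Sigma inverse-Wishart(I, df) (or independent
    half-normal SDs); residual SDs and sigma_obs uniform."""
    ll = 0.0
    ll += _logistic_logpdf(vr.mu[:4]).sum()
    ll += -0.5 * (vr.mu[4:] / 10.0) ** 2 @ np.ones(3) - 3 * np.log(10.0 * np.sqrt(2 * np.pi))
    for b in vr.beta.values():
        ll += -0.5 * (b / 10.0) ** 2 - np.log(10.0 * np.sqrt(2 * np.pi))
    # Sigma prior
    S = vr.Sigma
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return NEG_INF
    if config.sigma_prior == "invwishart":
        d, df = 7, config.iw_df
        Sinv = np.linalg.inv(S)
        ll += -0.5 * (df + d + 1) * logdet - 0.5 * np.trace(Sinv)
    else:  # diagonal half-normal, sd ~ HalfNormal(1)
        sd = np.sqrt(np.diag(S))
        ll += np.sum(-0.5 * sd**2)
    # MVN residual rows
    Sinv = np.linalg.inv(S)
    T = vr.eps.shape[0]
    quad = np.einsum("ti,ij,tj->", vr.eps, Sinv, vr.eps)
    ll += -0.5 * quad - 0.5 * T * (logdet + 7 * np.log(2 * np.pi))
    # Recapture block
    ll += _logistic_logpdf(rp.mu_p).sum()
    if np.any(rp.sigma_p <= 0) or np.any(rp.sigma_p >= 10):
        return NEG_INF
    if det_mask is None:
        det_mask = np.ones(rp.eps_p.shape[0], dtype=bool)
    e = rp.eps_p[det_mask]
    ll += float(
        np.sum(-0.5 * (e / rp.sigma_p) ** 2 - np.log(rp.sigma_p * np.sqrt(2 * np.pi)))
    )
    if not (0.001 < op.sigma_obs < 10):
        return NEG_INF
    return float(ll)


def joint_log_posterior(
    vr: VitalRateParams,
    rp: RecaptureParams,
    op: ObservationParams,
    latents: LatentStates,
    data: IPMData,
    config: ModelConfig | None = None,
) -> dict:
    """All blocks plus their sum; the decomposition is exposed for testing."""
    config = ModelConfig() if config is None else config
    det = data.detection_occasions()
    rates = compute_rates(vr, data.X, data.cov_names)
    p = detection_series(rp, det)
    parts = {
        "state": state_loglik(latents, rates),
        "obs": obs_loglik(data.counts, latents.B, op.sigma_obs),
        "cjs": cjs_loglik(data.marr, rates, p),
        "productivity": productivity_loglik(data.J, data.females_surveyed, rates["rho"]),
        "prior": prior_logdensity(vr, rp, op, config, det),
    }
    parts["total"] = sum(parts.values())
    return parts
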
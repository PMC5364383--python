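"""Posterior-predictive goodness-of-fit for the capture-recapture and
productivity blocks.

For each retained draw, an expected data set and a replicated data set are
generated at that draw's parameters; the Bayesian p-value is the fraction of
draws whose replicated discrepancy is at least the observed one.  Values near
0 or 1 indicate misfit.  No omnibus check is attempted for the state-space
block, where such measures are not well established.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GROUPS
from .mcmc import Posterior

__all__ = ["GofResult", "freeman_tukey_cjs", "chisq_productivity"]

EPS_GUARD = 1e-6  # fixed guard in the chi-square denominator


@dataclass
class GofResult:
    observed: np.ndarray  # per-draw observed discrepancy
    replicated: np.ndarray  # per-draw replicated discrepancy
    block: str

    @property
    def p_value(self) -> float:
        return float(np.mean(self.replicated >= self.observed))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"draw": np.arange(len(self.observed)),
             "observed_disc": self.observed,
             "replicated_disc": self.replicated}
        )


def _cell_prob_matrix(g: int, phi_j, phi_ad, p, T: int) -> np.ndarray:
    """(n_draws, T-1, T) cell probabilities for group g: first-recapture
    occasions 1..T-1 in columns 0..T-2, never-seen in the last column."""
    D = phi_ad.shape[0]
    s = g % 2
    juv = g < 2
    cells = np.zeros((D, T - 1, T))
    for i in range(T - 1):
        chi = np.ones(D)
        for j in range(i + 1, T):
            if juv and j == i + 1:
                ph = phi_j[:, s, i]
                pd_ = p[:, s, j]
            else:
                ph = phi_ad[:, s, j - 1]
                pd_ = p[:, 2 + s, j]
            chi = chi * ph
            cells[:, i, j - 1] = chi * pd_
            chi = chi * (1.0 - pd_)
        cells[:, i, T - 1] = 1.0 - cells[:, i, : T - 1].sum(axis=1)
    return np.clip(cells, 0.0, 1.0)


def freeman_tukey_cjs(posterior: Posterior, marrays=None, seed: int = 0) -> GofResult:
    """Freeman-Tukey discrepancy sum((sqrt(m) - sqrt(expected))^2) over
    m-array cells, with replicates drawn multinomially at each draw's
    parameters conditional on the observed release totals.

    ``marrays`` defaults to the data the posterior was fit to; passing a
    different m-array set scores that data against the fitted model.
    """
    data = posterior.data
    T = data.n_years
    marr = data.marr if marrays is None else marrays
    phi_j = posterior.stack("phi_j")
    phi_ad = posterior.stack("phi_ad")
    p = posterior.stack("p")
    D = phi_j.shape[0]
    rng = np.random.default_rng(seed)
    obs_disc = np.zeros(D)
    rep_disc = np.zeros(D)
    for gi, g in enumerate(GROUPS):
        cells = _cell_prob_matrix(gi, phi_j, phi_ad, p, T)
        rel = marr.releases[g]
        m = marr.m[g]
        for i in range(T - 1):
            if rel[i] == 0:
                continue  # zero-release rows contribute nothing
            expected = rel[i] * cells[:, i, :]
            obs_disc += ((np.sqrt(m[i]) - np.sqrt(expected)) ** 2).sum(axis=1)
            pv = cells[:, i, :]
            pv = pv / pv.sum(axis=1, keepdims=True)
            rep = rng.multinomial(int(rel[i]), pv)
            rep_disc += ((np.sqrt(rep) - np.sqrt(expected)) ** 2).sum(axis=1)
    return GofResult(observed=obs_disc, replicated=rep_disc, block="cjs")


def chisq_productivity(posterior: Posterior, productivity=None, seed: int = 0) -> GofResult:
    """Chi-square discrepancy sum((J - expected)^2 / (expected + guard)) for
    the Poisson fledgling-count model, conditional on surveyed females.

    ``productivity`` is an optional (J, females_surveyed) pair of arrays; it
    defaults to the data the posterior was fit to.
    """
    data = posterior.data
    if productivity is None:
        J_all, fem_all = data.J, data.females_surveyed
    else:
        J_all, fem_all = (np.asarray(a, dtype=float) for a in productivity)
    obs = np.isfinite(J_all) & np.isfinite(fem_all)
    J = J_all[obs]
    females = fem_all[obs]
    rho = posterior.stack("rho")[:, obs]
    expected = rho * females
    rng = np.random.default_rng(seed)
    rep = rng.poisson(expected)
    obs_disc = ((J - expected) ** 2 / (expected + EPS_GUARD)).sum(axis=1)
    rep_disc = ((rep - expected) ** 2 / (expected + EPS_GUARD)).sum(axis=1)
    return GofResult(observed=obs_disc, replicated=rep_disc, block="productivity")
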
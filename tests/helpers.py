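"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (latent-path
enumeration, dense grids, matrix powers) without touching the package's own
likelihood or sampling code paths.
"""

from __future__ import annotations

import numpy as np


def individual_cjs_loglik(enc, phi_j, phi_ad, p) -> float:
    """Sum of per-individual encounter-history log-probabilities, each
    computed by exhaustive enumeration of the unknown death time.

    phi_j, phi_ad: (2, T-1); p: (4, T) with groups (juv_f, juv_m, ad_f, ad_m).
    A bird marked as a juvenile uses phi_j for its first interval and the
    juvenile detection probability at its first possible re-encounter
    (age 1); everything else is adult.
    """
    T = enc.n_occasions
    total = 0.0
    for i in range(len(enc.ids)):
        h = enc.histories[i]
        s = 0 if enc.sex[i] == "f" else 1
        juv = enc.age_first[i] == "juvenile"
        f = int(np.argmax(h == 1))
        last = int(np.max(np.flatnonzero(h)))
        prob = 0.0
        for k in range(last, T):  # k = last occasion alive and present
            term = 1.0
            for t in range(f, k):  # survive intervals f..k-1
                term *= phi_j[s, t] if (juv and t == f) else phi_ad[s, t]
            if k < T - 1:  # die/emigrate in interval k -> k+1
                ph_k = phi_j[s, k] if (juv and k == f) else phi_ad[s, k]
                term *= 1.0 - ph_k
            for t in range(f + 1, k + 1):  # detection outcomes while alive
                pd = p[s, t] if (juv and t == f + 1) else p[2 + s, t]
                term *= pd if h[t] == 1 else 1.0 - pd
            prob += term
        if prob <= 0:
            return -np.inf
        total += np.log(prob)
    return total


def random_encounters(rng, n_ind=6, T=4):
    """A random valid encounter data set (every bird seen at least once)."""
    from fullcycle.io import EncounterData

    ids, sex, age, rows = [], [], [], []
    for i in range(n_ind):
        f = rng.integers(0, T - 1)
        h = np.zeros(T, dtype=np.int64)
        h[f] = 1
        for t in range(f + 1, T):
            h[t] = rng.integers(0, 2)
        ids.append(str(i))
        sex.append(rng.choice(["f", "m"]))
        age.append(rng.choice(["juvenile", "adult"]))
        rows.append(h)
    return EncounterData(
        ids=np.array(ids), sex=np.array(sex), age_first=np.array(age),
        histories=np.array(rows),
    )


def random_rates(rng, T):
    """Random smooth rate/detection series for oracle comparisons."""
    phi_j = rng.uniform(0.1, 0.9, (2, T - 1))
    phi_ad = rng.uniform(0.1, 0.9, (2, T - 1))
    p = rng.uniform(0.2, 0.95, (4, T))
    p[:, 0] = 0.0
    rates = {
        "phi_j": phi_j,
        "phi_ad": phi_ad,
        "rho": rng.uniform(1, 4, T),
        "iota": rng.uniform(1, 10, (2, T)),
    }
    return rates, p


def dominant_eigenvalue_by_power(rho, phi_j_f, phi_ad_f, phi_ad_m, phi_j_m, n_pow=200):
    """Dominant eigenvalue of the deterministic two-sex projection, computed
    by repeated matrix multiplication (power iteration), not an eig call."""
    A = np.array(
        [
            [0.5 * rho * phi_j_f + phi_ad_f, 0.0],
            [0.5 * rho * phi_j_m, phi_ad_m],
        ]
    )
    v = np.ones(2)
    lam = 1.0
    for _ in range(n_pow):
        w = A @ v
        lam = np.linalg.norm(w) / np.linalg.norm(v)
        v = w / np.linalg.norm(w)
    return lam


def grid_cjs_posterior(marr_small, rel_small, n_grid=160):
    """Dense-grid posterior over constant (phi, p) for a single-group CJS
    m-array under uniform priors; computed with a standalone likelihood."""
    T = marr_small.shape[1]
    phis = (np.arange(n_grid) + 0.5) / n_grid
    ps = (np.arange(n_grid) + 0.5) / n_grid
    logpost = np.zeros((n_grid, n_grid))
    for a, phi in enumerate(phis):
        for b, pdet in enumerate(ps):
            ll = 0.0
            for i in range(T - 1):
                if rel_small[i] == 0:
                    continue
                csum = 0.0
                chi = 1.0
                for j in range(i + 1, T):
                    chi *= phi
                    cell = chi * pdet
                    if marr_small[i, j - 1] > 0:
                        ll += marr_small[i, j - 1] * np.log(cell)
                    csum += cell
                    chi *= 1.0 - pdet
                nev = marr_small[i, T - 1]
                if nev > 0:
                    ll += nev * np.log(1.0 - csum)
            logpost[a, b] = ll
    logpost -= logpost.max()
    post = np.exp(logpost)
    return phis, ps, post / post.sum()
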
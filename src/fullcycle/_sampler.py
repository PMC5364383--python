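"""Compiled Metropolis-within-Gibbs core for the integrated population model.

One chain = one call to :func:`run_chain`.  Discrete latent abundances are
updated by +/-k integer random walks, continuous blocks by adaptive Gaussian
random walks (scales tuned to ~0.44 acceptance during burn-in, frozen after),
and the residual covariance by a conjugate inverse-Wishart draw given the
residual matrix.  Every update evaluates only the terms of the joint density
it can change; the semantics are mirrored 1:1 by the numpy reference in
:mod:`fullcycle.model`, and the two are held equal by test.

Array conventions match :mod:`fullcycle.model`: sexes 0=f/1=m, groups
(juv_f, juv_m, ad_f, ad_m), rates (phi_j_f, phi_j_m, phi_ad_f, phi_ad_m,
rho, iota_f, iota_m); residual row t drives survival t->t+1, fecundity t and
immigrant arrivals t+1.
"""

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf
INIT_MAX = 300
LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# scalar log-pmfs / pdfs


@njit(cache=True)
def _lbinom(k, n, p):
    if k < 0 or n < 0 or k > n or p < 0.0 or p > 1.0:
        return NEG_INF
    if p == 0.0:
        return 0.0 if k == 0 else NEG_INF
    if p == 1.0:
        return 0.0 if k == n else NEG_INF
    return (
        math.lgamma(n + 1.0)
        - math.lgamma(k + 1.0)
        - math.lgamma(n - k + 1.0)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def _lpois(k, lam):
    if k < 0 or lam < 0.0:
        return NEG_INF
    if lam == 0.0:
        return 0.0 if k == 0 else NEG_INF
    return k * math.log(lam) - lam - math.lgamma(k + 1.0)


@njit(cache=True)
def _logistic_lpdf(x):
    ax = abs(x)
    return -ax - 2.0 * math.log1p(math.exp(-ax))


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# CJS pieces


@njit(cache=True)
def _cjs_row_ll(g, i, marr, rel, phi_j, phi_ad, p, T):
    """Multinomial log-likelihood (no coefficient) of release row i, group g."""
    if rel[g, i] == 0:
        return 0.0
    s = g % 2
    juv = g < 2
    ll = 0.0
    chi = 1.0
    csum = 0.0
    for j in range(i + 1, T):
        if juv and j == i + 1:
            ph = phi_j[s, i]
            pd = p[s, j]
        else:
            ph = phi_ad[s, j - 1]
            pd = p[2 + s, j]
        chi *= ph
        cell = chi * pd
        mij = marr[g, i, j - 1]
        if mij > 0:
            if cell <= 0.0:
                return NEG_INF
            ll += mij * math.log(cell)
        csum += cell
        chi *= 1.0 - pd
    nev = marr[g, i, T - 1]
    if nev > 0:
        pn = 1.0 - csum
        if pn <= 0.0:
            return NEG_INF
        ll += nev * math.log(pn)
    return ll


@njit(cache=True)
def _cjs_group_ll(g, marr, rel, phi_j, phi_ad, p, T):
    ll = 0.0
    for i in range(T - 1):
        ll += _cjs_row_ll(g, i, marr, rel, phi_j, phi_ad, p, T)
    return ll


@njit(cache=True)
def _cjs_sex_ll(s, marr, rel, phi_j, phi_ad, p, T):
    return _cjs_group_ll(s, marr, rel, phi_j, phi_ad, p, T) + _cjs_group_ll(
        2 + s, marr, rel, phi_j, phi_ad, p, T
    )


@njit(cache=True)
def _cjs_sex_ll_rows(s, i_max, marr, rel, phi_j, phi_ad, p, T):
    """Rows 0..i_max of both m-arrays of sex s: the only rows whose cell
    probabilities involve adult survival or adult detection at year > i_max."""
    ll = 0.0
    top = min(i_max, T - 2)
    for i in range(top + 1):
        ll += _cjs_row_ll(s, i, marr, rel, phi_j, phi_ad, p, T)
        ll += _cjs_row_ll(2 + s, i, marr, rel, phi_j, phi_ad, p, T)
    return ll


# ---------------------------------------------------------------------------
# local likelihood terms


@njit(cache=True)
def _obs_term(s, t, B, logC, obs_mask, sigma_obs):
    if obs_mask[s, t] == 0:
        return 0.0
    b = B[s, t]
    if b <= 0:
        return NEG_INF
    z = (logC[s, t] - math.log(b)) / sigma_obs
    return -0.5 * z * z - math.log(sigma_obs) - LOG_SQRT_2PI


@njit(cache=True)
def _prod_term(t, rho, J, Cf, prod_mask):
    if prod_mask[t] == 0:
        return 0.0
    return _lpois(J[t], rho[t] * Cf[t])


@njit(cache=True)
def _around_B(s, t, R, S, I, B, Ftot, phi_ad, rho, logC, obs_mask, sigma_obs, T):
    """Terms that depend on B[s, t] other than the pmf of the stage itself."""
    ll = _obs_term(s, t, B, logC, obs_mask, sigma_obs)
    if t < T - 1:
        ll += _lbinom(S[s, t + 1], B[s, t], phi_ad[s, t])
    if s == 0:
        ll += _lpois(Ftot[t], rho[t] * B[0, t])
    return ll


@njit(cache=True)
def _stage_pmf(stage, s, t, val, R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota):
    """Log-pmf of stage value itself: 0=R, 1=S, 2=I."""
    if t == 0:
        return 0.0 if 0 <= val <= INIT_MAX else NEG_INF
    if stage == 0:
        ftrials = Ff[t - 1] if s == 0 else Ftot[t - 1] - Ff[t - 1]
        return _lbinom(val, ftrials, phi_j[s, t - 1])
    if stage == 1:
        return _lbinom(val, B[s, t - 1], phi_ad[s, t - 1])
    return _lpois(val, iota[s, t])


# ---------------------------------------------------------------------------
# rate cache reconstruction


@njit(cache=True)
def _eta(ri, t, mu, beta, brate, bcov, X, eps):
    v = mu[ri] + eps[t, ri]
    for k in range(brate.shape[0]):
        if brate[k] == ri:
            v += beta[k] * X[t, bcov[k]]
    return v


@njit(cache=True)
def _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T):
    v = _eta(ri, t, mu, beta, brate, bcov, X, eps)
    if ri < 2:
        if t < T - 1:
            phi_j[ri, t] = _expit(v)
    elif ri < 4:
        if t < T - 1:
            phi_ad[ri - 2, t] = _expit(v)
    elif ri == 4:
        rho[t] = math.exp(v)
    else:
        if t < T - 1:
            iota[ri - 5, t + 1] = math.exp(v)


@njit(cache=True)
def _rebuild_rates(mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T):
    for ri in range(7):
        for t in range(T):
            _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)


@njit(cache=True)
def _rebuild_p(mu_p, eps_p, det_mask, p, T):
    for g in range(4):
        for t in range(T):
            p[g, t] = _expit(mu_p[g] + eps_p[t, g]) if det_mask[t] == 1 else 0.0


@njit(cache=True)
def _row_quad(t, eps, Sinv):
    q = 0.0
    for a in range(7):
        for b in range(7):
            q += eps[t, a] * Sinv[a, b] * eps[t, b]
    return q


# ---------------------------------------------------------------------------
# whole-likelihood pieces used by the mu/beta/sigma updates


@njit(cache=True)
def _rate_ll(ri, marr, rel, R, S, I, B, Ftot, Ff, phi_j, phi_ad, rho, iota, p,
             J, Cf, prod_mask, T):
    """All likelihood terms touched by the series of rate ri."""
    ll = 0.0
    if ri < 2:
        s = ri
        for t in range(T - 1):
            ftrials = Ff[t] if s == 0 else Ftot[t] - Ff[t]
            ll += _lbinom(R[s, t + 1], ftrials, phi_j[s, t])
        ll += _cjs_group_ll(s, marr, rel, phi_j, phi_ad, p, T)
    elif ri < 4:
        s = ri - 2
        for t in range(T - 1):
            ll += _lbinom(S[s, t + 1], B[s, t], phi_ad[s, t])
        ll += _cjs_sex_ll(s, marr, rel, phi_j, phi_ad, p, T)
    elif ri == 4:
        for t in range(T):
            ll += _lpois(Ftot[t], rho[t] * B[0, t])
            ll += _prod_term(t, rho, J, Cf, prod_mask)
    else:
        s = ri - 5
        for t in range(1, T):
            ll += _lpois(I[s, t], iota[s, t])
    return ll


@njit(cache=True)
def _full_loglik(marr, rel, logC, obs_mask, J, Cf, prod_mask,
                 R, S, I, B, Ftot, Ff, phi_j, phi_ad, rho, iota, p, sigma_obs, T):
    """State + observation + CJS + productivity log-likelihood (no priors)."""
    ll = 0.0
    for s in range(2):
        for t in range(T):
            if t == 0:
                for val in (R[s, 0], S[s, 0], I[s, 0]):
                    ll += -math.log(INIT_MAX + 1.0) if 0 <= val <= INIT_MAX else NEG_INF
            else:
                ftrials = Ff[t - 1] if s == 0 else Ftot[t - 1] - Ff[t - 1]
                ll += _lbinom(R[s, t], ftrials, phi_j[s, t - 1])
                ll += _lbinom(S[s, t], B[s, t - 1], phi_ad[s, t - 1])
                ll += _lpois(I[s, t], iota[s, t])
            ll += _obs_term(s, t, B, logC, obs_mask, sigma_obs)
    for t in range(T):
        ll += _lpois(Ftot[t], rho[t] * B[0, t])
        ll += _lbinom(Ff[t], Ftot[t], 0.5)
        ll += _prod_term(t, rho, J, Cf, prod_mask)
    for g in range(4):
        ll += _cjs_group_ll(g, marr, rel, phi_j, phi_ad, p, T)
    return ll


# ---------------------------------------------------------------------------
# conjugate inverse-Wishart draw for Sigma


@njit(cache=True)
def _draw_sigma_iw(eps, iw_df, T):
    d = 7
    S_post = np.eye(d)
    for t in range(T):
        for a in range(d):
            for b in range(d):
                S_post[a, b] += eps[t, a] * eps[t, b]
    df = iw_df + T
    L = np.linalg.cholesky(np.linalg.inv(S_post))
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = math.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    LA = L @ A
    W = LA @ LA.T  # precision draw ~ Wishart(df, S_post^{-1})
    Sigma = np.linalg.inv(W)
    return Sigma, W


# ---------------------------------------------------------------------------
# the chain


@njit(cache=True)
def run_chain(
    seed, n_iter, n_burnin, thin,
    marr, rel, logC, obs_mask, J, Cf, prod_mask, X, det_mask,
    brate, bcov,
    mu, beta, eps, Sigma, mu_p, eps_p, sigma_p, sigma_obs,
    R, S, I, Ftot, Ff,
    sigma_prior_diag, latents_fixed, eps_fixed,
    out_mu, out_beta, out_mup, out_sp, out_so, out_Sigma,
    out_phi_j, out_phi_ad, out_rho, out_iota, out_p,
    out_R, out_S, out_I, out_F, out_Ff,
):
    """Run one MCMC chain in place; state arrays are mutated and draws written
    into the ``out_*`` arrays.  Returns mean acceptance rates per block."""
    np.random.seed(seed)
    T = logC.shape[1]
    nb = beta.shape[0]
    iw_df = 9.0

    B = R + S + I
    phi_j = np.zeros((2, T - 1))
    phi_ad = np.zeros((2, T - 1))
    rho = np.zeros(T)
    iota = np.zeros((2, T))
    p = np.zeros((4, T))
    _rebuild_rates(mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)
    _rebuild_p(mu_p, eps_p, det_mask, p, T)
    Sinv = np.linalg.inv(Sigma)

    # adaptive proposal scales
    sc_eps = np.full((T, 7), 0.3)
    sc_mu = np.full(7, 0.1)
    sc_beta = np.full(nb, 0.1)
    sc_mup = np.full(4, 0.2)
    sc_epsp = np.full((T, 4), 0.5)
    sc_sp = np.full(4, 0.3)
    sc_so = 0.3
    sc_lat = np.full((5, 2, T), 3.0)  # stage x sex x year (stages 3,4: F, Ff at sex 0)
    acc = np.zeros(8)
    tries = np.zeros(8)
    a_eps = np.zeros((T, 7)); n_eps = np.zeros((T, 7))
    a_mu = np.zeros(7); n_mu = np.zeros(7)
    a_beta = np.zeros(nb); n_beta = np.zeros(nb)
    a_mup = np.zeros(4); n_mup = np.zeros(4)
    a_epsp = np.zeros((T, 4)); n_epsp = np.zeros((T, 4))
    a_sp = np.zeros(4); n_sp = np.zeros(4)
    a_so = 0.0; n_so = 0.0
    a_lat = np.zeros((5, 2, T)); n_lat = np.zeros((5, 2, T))

    d_idx = 0
    n_keep = out_mu.shape[0]

    for it in range(n_iter):
        # ---------------- discrete latents ----------------
        if not latents_fixed:
            for t in range(T):
                for s in range(2):
                    for stage in range(3):
                        arr = R if stage == 0 else (S if stage == 1 else I)
                        step = int(sc_lat[stage, s, t]) + 1
                        d = np.random.randint(1, step + 1)
                        if np.random.random() < 0.5:
                            d = -d
                        old = arr[s, t]
                        new = old + d
                        n_lat[stage, s, t] += 1.0
                        if new < 0:
                            continue
                        ll0 = _stage_pmf(stage, s, t, old, R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota) \
                            + _around_B(s, t, R, S, I, B, Ftot, phi_ad, rho, logC, obs_mask, sigma_obs, T)
                        if stage == 0 and t < T - 1:
                            pass  # R feeds B only; recruit pmf of t+1 unaffected by R[s,t]
                        arr[s, t] = new
                        B[s, t] = R[s, t] + S[s, t] + I[s, t]
                        ll1 = _stage_pmf(stage, s, t, new, R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota) \
                            + _around_B(s, t, R, S, I, B, Ftot, phi_ad, rho, logC, obs_mask, sigma_obs, T)
                        if math.log(np.random.random()) < ll1 - ll0:
                            a_lat[stage, s, t] += 1.0
                        else:
                            arr[s, t] = old
                            B[s, t] = R[s, t] + S[s, t] + I[s, t]

                # composition-preserving pair moves: exchange between stages at
                # fixed B (keeps the count term unchanged, so the R/S/I split
                # mixes even when sigma_obs is small and B is pinned to C)
                for s in range(2):
                    pair = np.random.randint(0, 3)  # 0: R<->I, 1: S<->I, 2: R<->S
                    d = 1 + np.random.randint(0, 2)
                    if np.random.random() < 0.5:
                        d = -d
                    if pair == 0:
                        a1, a2 = 0, 2
                    elif pair == 1:
                        a1, a2 = 1, 2
                    else:
                        a1, a2 = 0, 1
                    arr1 = R if a1 == 0 else S
                    arr2 = I if a2 == 2 else S
                    v1, v2 = arr1[s, t] + d, arr2[s, t] - d
                    if v1 >= 0 and v2 >= 0:
                        ll0 = _stage_pmf(a1, s, t, arr1[s, t], R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota) \
                            + _stage_pmf(a2, s, t, arr2[s, t], R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota)
                        ll1 = _stage_pmf(a1, s, t, v1, R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota) \
                            + _stage_pmf(a2, s, t, v2, R, S, I, B, Ftot, Ff, phi_j, phi_ad, iota)
                        if math.log(np.random.random()) < ll1 - ll0:
                            arr1[s, t] = v1
                            arr2[s, t] = v2

                # F_tot[t]
                step = int(sc_lat[3, 0, t]) + 1
                d = np.random.randint(1, step + 1)
                if np.random.random() < 0.5:
                    d = -d
                old = Ftot[t]
                new = old + d
                n_lat[3, 0, t] += 1.0
                if new >= Ff[t]:
                    ll0 = _lpois(old, rho[t] * B[0, t]) + _lbinom(Ff[t], old, 0.5)
                    ll1 = _lpois(new, rho[t] * B[0, t]) + _lbinom(Ff[t], new, 0.5)
                    if t < T - 1:
                        ll0 += _lbinom(R[1, t + 1], old - Ff[t], phi_j[1, t])
                        ll1 += _lbinom(R[1, t + 1], new - Ff[t], phi_j[1, t])
                    if math.log(np.random.random()) < ll1 - ll0:
                        Ftot[t] = new
                        a_lat[3, 0, t] += 1.0

                # F_f[t]
                step = int(sc_lat[4, 0, t]) + 1
                d = np.random.randint(1, step + 1)
                if np.random.random() < 0.5:
                    d = -d
                old = Ff[t]
                new = old + d
                n_lat[4, 0, t] += 1.0
                if 0 <= new <= Ftot[t]:
                    ll0 = _lbinom(old, Ftot[t], 0.5)
                    ll1 = _lbinom(new, Ftot[t], 0.5)
                    if t < T - 1:
                        ll0 += _lbinom(R[0, t + 1], old, phi_j[0, t]) + _lbinom(R[1, t + 1], Ftot[t] - old, phi_j[1, t])
                        ll1 += _lbinom(R[0, t + 1], new, phi_j[0, t]) + _lbinom(R[1, t + 1], Ftot[t] - new, phi_j[1, t])
                    if math.log(np.random.random()) < ll1 - ll0:
                        Ff[t] = new
                        a_lat[4, 0, t] += 1.0

        # ---------------- temporal residuals eps ----------------
        for t in range(0 if not eps_fixed else T, T):
            for ri in range(7):
                old = eps[t, ri]
                prop = old + sc_eps[t, ri] * np.random.standard_normal()
                n_eps[t, ri] += 1.0
                ll0 = -0.5 * _row_quad(t, eps, Sinv)
                if ri < 2:
                    s = ri
                    if t < T - 1:
                        ftrials = Ff[t] if s == 0 else Ftot[t] - Ff[t]
                        ll0 += _lbinom(R[s, t + 1], ftrials, phi_j[s, t])
                        ll0 += _cjs_row_ll(s, t, marr, rel, phi_j, phi_ad, p, T)
                elif ri < 4:
                    s = ri - 2
                    if t < T - 1:
                        ll0 += _lbinom(S[s, t + 1], B[s, t], phi_ad[s, t])
                        ll0 += _cjs_sex_ll_rows(s, t, marr, rel, phi_j, phi_ad, p, T)
                elif ri == 4:
                    ll0 += _lpois(Ftot[t], rho[t] * B[0, t]) + _prod_term(t, rho, J, Cf, prod_mask)
                else:
                    s = ri - 5
                    if t < T - 1:
                        ll0 += _lpois(I[s, t + 1], iota[s, t + 1])
                eps[t, ri] = prop
                _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)
                ll1 = -0.5 * _row_quad(t, eps, Sinv)
                if ri < 2:
                    s = ri
                    if t < T - 1:
                        ftrials = Ff[t] if s == 0 else Ftot[t] - Ff[t]
                        ll1 += _lbinom(R[s, t + 1], ftrials, phi_j[s, t])
                        ll1 += _cjs_row_ll(s, t, marr, rel, phi_j, phi_ad, p, T)
                elif ri < 4:
                    s = ri - 2
                    if t < T - 1:
                        ll1 += _lbinom(S[s, t + 1], B[s, t], phi_ad[s, t])
                        ll1 += _cjs_sex_ll_rows(s, t, marr, rel, phi_j, phi_ad, p, T)
                elif ri == 4:
                    ll1 += _lpois(Ftot[t], rho[t] * B[0, t]) + _prod_term(t, rho, J, Cf, prod_mask)
                else:
                    s = ri - 5
                    if t < T - 1:
                        ll1 += _lpois(I[s, t + 1], iota[s, t + 1])
                if math.log(np.random.random()) < ll1 - ll0:
                    a_eps[t, ri] += 1.0
                else:
                    eps[t, ri] = old
                    _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)

        # ---------------- means mu and slopes beta ----------------
        for ri in range(7):
            old = mu[ri]
            prop = old + sc_mu[ri] * np.random.standard_normal()
            n_mu[ri] += 1.0
            pr0 = _logistic_lpdf(old) if ri < 4 else -0.5 * (old / 10.0) ** 2
            pr1 = _logistic_lpdf(prop) if ri < 4 else -0.5 * (prop / 10.0) ** 2
            ll0 = _rate_ll(ri, marr, rel, R, S, I, B, Ftot, Ff, phi_j, phi_ad, rho, iota, p, J, Cf, prod_mask, T)
            mu[ri] = prop
            for t in range(T):
                _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)
            ll1 = _rate_ll(ri, marr, rel, R, S, I, B, Ftot, Ff, phi_j, phi_ad, rho, iota, p, J, Cf, prod_mask, T)
            if math.log(np.random.random()) < (ll1 + pr1) - (ll0 + pr0):
                a_mu[ri] += 1.0
            else:
                mu[ri] = old
                for t in range(T):
                    _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)

        for k in range(nb):
            ri = brate[k]
            old = beta[k]
            prop = old + sc_beta[k] * np.random.standard_normal()
            n_beta[k] += 1.0
            pr0 = -0.5 * (old / 10.0) ** 2
            pr1 = -0.5 * (prop / 10.0) ** 2
            ll0 = _rate_ll(ri, marr, rel, R, S, I, B, Ftot, Ff, phi_j, phi_ad, rho, iota, p, J, Cf, prod_mask, T)
            beta[k] = prop
            for t in range(T):
                _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)
            ll1 = _rate_ll(ri, marr, rel, R, S, I, B, Ftot, Ff, phi_j, phi_ad, rho, iota, p, J, Cf, prod_mask, T)
            if math.log(np.random.random()) < (ll1 + pr1) - (ll0 + pr0):
                a_beta[k] += 1.0
            else:
                beta[k] = old
                for t in range(T):
                    _set_rate(ri, t, mu, beta, brate, bcov, X, eps, phi_j, phi_ad, rho, iota, T)

        # translation moves: shift a mean (or slope) and counter-shift the
        # residual column so every rate series — and hence the likelihood —
        # is unchanged; only the priors enter the acceptance ratio.  These
        # decorrelate the means from their residuals (non-centering move).
        for ri in range(0 if not eps_fixed else 7, 7):
            delta = 0.3 * np.random.standard_normal()
            prop = mu[ri] + delta
            pr0 = _logistic_lpdf(mu[ri]) if ri < 4 else -0.5 * (mu[ri] / 10.0) ** 2
            pr1 = _logistic_lpdf(prop) if ri < 4 else -0.5 * (prop / 10.0) ** 2
            q0 = 0.0
            for t in range(T):
                q0 += _row_quad(t, eps, Sinv)
            for t in range(T):
                eps[t, ri] -= delta
            q1 = 0.0
            for t in range(T):
                q1 += _row_quad(t, eps, Sinv)
            if math.log(np.random.random()) < (pr1 - 0.5 * q1) - (pr0 - 0.5 * q0):
                mu[ri] = prop
            else:
                for t in range(T):
                    eps[t, ri] += delta

        for k in range(0 if not eps_fixed else nb, nb):
            ri = brate[k]
            ci = bcov[k]
            delta = 0.3 * np.random.standard_normal()
            prop = beta[k] + delta
            pr0 = -0.5 * (beta[k] / 10.0) ** 2
            pr1 = -0.5 * (prop / 10.0) ** 2
            q0 = 0.0
            for t in range(T):
                q0 += _row_quad(t, eps, Sinv)
            for t in range(T):
                eps[t, ri] -= delta * X[t, ci]
            q1 = 0.0
            for t in range(T):
                q1 += _row_quad(t, eps, Sinv)
            if math.log(np.random.random()) < (pr1 - 0.5 * q1) - (pr0 - 0.5 * q0):
                beta[k] = prop
            else:
                for t in range(T):
                    eps[t, ri] += delta * X[t, ci]

        # same translation move for the detection means
        for g in range(4):
            delta = 0.3 * np.random.standard_normal()
            prop = mu_p[g] + delta
            pr0 = _logistic_lpdf(mu_p[g])
            pr1 = _logistic_lpdf(prop)
            for t in range(T):
                if det_mask[t] == 1:
                    pr0 += -0.5 * (eps_p[t, g] / sigma_p[g]) ** 2
                    pr1 += -0.5 * ((eps_p[t, g] - delta) / sigma_p[g]) ** 2
            if math.log(np.random.random()) < pr1 - pr0:
                mu_p[g] = prop
                for t in range(T):
                    if det_mask[t] == 1:
                        eps_p[t, g] -= delta

        # ---------------- detection block ----------------
        for g in range(4):
            old = mu_p[g]
            prop = old + sc_mup[g] * np.random.standard_normal()
            n_mup[g] += 1.0
            if g < 2:
                ll0 = _cjs_group_ll(g, marr, rel, phi_j, phi_ad, p, T)
            else:
                ll0 = _cjs_sex_ll(g - 2, marr, rel, phi_j, phi_ad, p, T)
            pr0 = _logistic_lpdf(old)
            mu_p[g] = prop
            for t in range(T):
                p[g, t] = _expit(mu_p[g] + eps_p[t, g]) if det_mask[t] == 1 else 0.0
            if g < 2:
                ll1 = _cjs_group_ll(g, marr, rel, phi_j, phi_ad, p, T)
            else:
                ll1 = _cjs_sex_ll(g - 2, marr, rel, phi_j, phi_ad, p, T)
            pr1 = _logistic_lpdf(prop)
            if math.log(np.random.random()) < (ll1 + pr1) - (ll0 + pr0):
                a_mup[g] += 1.0
            else:
                mu_p[g] = old
                for t in range(T):
                    p[g, t] = _expit(mu_p[g] + eps_p[t, g]) if det_mask[t] == 1 else 0.0

        for t in range(T):
            if det_mask[t] == 0:
                continue
            for g in range(4):
                old = eps_p[t, g]
                prop = old + sc_epsp[t, g] * np.random.standard_normal()
                n_epsp[t, g] += 1.0
                if g < 2:
                    ll0 = _cjs_row_ll(g, t - 1, marr, rel, phi_j, phi_ad, p, T)
                else:
                    ll0 = _cjs_sex_ll_rows(g - 2, t - 1, marr, rel, phi_j, phi_ad, p, T)
                pr0 = -0.5 * (old / sigma_p[g]) ** 2
                eps_p[t, g] = prop
                p[g, t] = _expit(mu_p[g] + eps_p[t, g])
                if g < 2:
                    ll1 = _cjs_row_ll(g, t - 1, marr, rel, phi_j, phi_ad, p, T)
                else:
                    ll1 = _cjs_sex_ll_rows(g - 2, t - 1, marr, rel, phi_j, phi_ad, p, T)
                pr1 = -0.5 * (prop / sigma_p[g]) ** 2
                if math.log(np.random.random()) < (ll1 + pr1) - (ll0 + pr0):
                    a_epsp[t, g] += 1.0
                else:
                    eps_p[t, g] = old
                    p[g, t] = _expit(mu_p[g] + eps_p[t, g])

        # sigma_p: random walk under U(0, 10) prior
        n_det = 0
        for t in range(T):
            if det_mask[t] == 1:
                n_det += 1
        for g in range(4):
            old = sigma_p[g]
            prop = old + sc_sp[g] * np.random.standard_normal()
            n_sp[g] += 1.0
            if prop <= 0.0 or prop >= 10.0:
                continue
            ss = 0.0
            for t in range(T):
                if det_mask[t] == 1:
                    ss += eps_p[t, g] ** 2
            ll0 = -0.5 * ss / old**2 - n_det * math.log(old)
            ll1 = -0.5 * ss / prop**2 - n_det * math.log(prop)
            if math.log(np.random.random()) < ll1 - ll0:
                sigma_p[g] = prop
                a_sp[g] += 1.0

        # sigma_obs: random walk under U(0.001, 10) prior
        old = sigma_obs
        prop = old + sc_so * np.random.standard_normal()
        n_so += 1.0
        if 0.001 < prop < 10.0:
            ll0 = 0.0
            ll1 = 0.0
            for s in range(2):
                for t in range(T):
                    ll0 += _obs_term(s, t, B, logC, obs_mask, old)
                    ll1 += _obs_term(s, t, B, logC, obs_mask, prop)
            if math.log(np.random.random()) < ll1 - ll0:
                sigma_obs = prop
                a_so += 1.0

        # ---------------- Sigma ----------------
        if sigma_prior_diag:
            # independent half-normal SDs: random walk on each log-sd
            for rj in range(7):
                sd_old = math.sqrt(Sigma[rj, rj])
                sd_prop = sd_old * math.exp(0.2 * np.random.standard_normal())
                ss = 0.0
                for t in range(T):
                    ss += eps[t, rj] ** 2
                ll0 = -0.5 * ss / sd_old**2 - T * math.log(sd_old) - 0.5 * sd_old**2 + math.log(sd_old)
                ll1 = -0.5 * ss / sd_prop**2 - T * math.log(sd_prop) - 0.5 * sd_prop**2 + math.log(sd_prop)
                if math.log(np.random.random()) < ll1 - ll0:
                    Sigma[rj, rj] = sd_prop**2
            Sinv = np.linalg.inv(Sigma)
        else:
            Sigma, Sinv = _draw_sigma_iw(eps, iw_df, T)

        # ---------------- adaptation (burn-in only) ----------------
        if it < n_burnin and (it + 1) % 50 == 0:
            gain = 0.3
            for t in range(T):
                for ri in range(7):
                    if n_eps[t, ri] > 0:
                        sc_eps[t, ri] *= math.exp(gain * (a_eps[t, ri] / n_eps[t, ri] - 0.44))
                    a_eps[t, ri] = 0.0; n_eps[t, ri] = 0.0
                for g in range(4):
                    if n_epsp[t, g] > 0:
                        sc_epsp[t, g] *= math.exp(gain * (a_epsp[t, g] / n_epsp[t, g] - 0.44))
                    a_epsp[t, g] = 0.0; n_epsp[t, g] = 0.0
            for ri in range(7):
                if n_mu[ri] > 0:
                    sc_mu[ri] *= math.exp(gain * (a_mu[ri] / n_mu[ri] - 0.44))
                a_mu[ri] = 0.0; n_mu[ri] = 0.0
            for k in range(nb):
                if n_beta[k] > 0:
                    sc_beta[k] *= math.exp(gain * (a_beta[k] / n_beta[k] - 0.44))
                a_beta[k] = 0.0; n_beta[k] = 0.0
            for g in range(4):
                if n_mup[g] > 0:
                    sc_mup[g] *= math.exp(gain * (a_mup[g] / n_mup[g] - 0.44))
                a_mup[g] = 0.0; n_mup[g] = 0.0
                if n_sp[g] > 0:
                    sc_sp[g] *= math.exp(gain * (a_sp[g] / n_sp[g] - 0.44))
                a_sp[g] = 0.0; n_sp[g] = 0.0
            if n_so > 0:
                sc_so *= math.exp(gain * (a_so / n_so - 0.44))
            a_so = 0.0; n_so = 0.0
            for stage in range(5):
                for s in range(2):
                    for t in range(T):
                        if n_lat[stage, s, t] > 0:
                            r = a_lat[stage, s, t] / n_lat[stage, s, t]
                            sc_lat[stage, s, t] = min(
                                60.0, max(1.0, sc_lat[stage, s, t] * math.exp(gain * (r - 0.44)))
                            )
                        a_lat[stage, s, t] = 0.0; n_lat[stage, s, t] = 0.0

        # ---------------- retain draw ----------------
        if it >= n_burnin and (it - n_burnin) % thin == thin - 1 and d_idx < n_keep:
            for ri in range(7):
                out_mu[d_idx, ri] = mu[ri]
            for k in range(nb):
                out_beta[d_idx, k] = beta[k]
            for g in range(4):
                out_mup[d_idx, g] = mu_p[g]
                out_sp[d_idx, g] = sigma_p[g]
            out_so[d_idx] = sigma_obs
            for a in range(7):
                for b in range(7):
                    out_Sigma[d_idx, a, b] = Sigma[a, b]
            for s in range(2):
                for t in range(T - 1):
                    out_phi_j[d_idx, s, t] = phi_j[s, t]
                    out_phi_ad[d_idx, s, t] = phi_ad[s, t]
                for t in range(T):
                    out_iota[d_idx, s, t] = iota[s, t]
                    out_R[d_idx, s, t] = R[s, t]
                    out_S[d_idx, s, t] = S[s, t]
                    out_I[d_idx, s, t] = I[s, t]
            for t in range(T):
                out_rho[d_idx, t] = rho[t]
                out_F[d_idx, t] = Ftot[t]
                out_Ff[d_idx, t] = Ff[t]
                for g in range(4):
                    out_p[d_idx, g, t] = p[g, t]
            d_idx += 1

    return d_idx


# ---------------------------------------------------------------------------
# small auxiliary samplers (shared schedule semantics)


@njit(cache=True)
def scalar_normal_chain(seed, n_iter, n_burnin, thin, out):
    """Random-walk Metropolis on a standard normal target; used to exercise
    the chain schedule (burn-in, thinning, retention) at full length."""
    np.random.seed(seed)
    x = 0.0
    d = 0
    n_keep = out.shape[0]
    for it in range(n_iter):
        prop = x + 2.4 * np.random.standard_normal()
        if math.log(np.random.random()) < 0.5 * (x * x - prop * prop):
            x = prop
        if it >= n_burnin and (it - n_burnin) % thin == thin - 1 and d < n_keep:
            out[d] = x
            d += 1
    return d


@njit(cache=True)
def cjs_phi_p_chain(seed, n_iter, n_burnin, thin, marr, rel, out_phi, out_p):
    """Metropolis sampler for a single-group CJS model with constant phi, p
    under uniform priors.  Shares the likelihood kernel of the full model."""
    np.random.seed(seed)
    T = marr.shape[2]
    phi_j = np.full((2, T - 1), 0.5)
    phi_ad = np.full((2, T - 1), 0.5)
    p = np.full((4, T), 0.5)
    p[:, 0] = 0.0
    phi = 0.5
    pdet = 0.5
    n_keep = out_phi.shape[0]
    d = 0
    ll = _cjs_group_ll(2, marr, rel, phi_j, phi_ad, p, T)
    for it in range(n_iter):
        for which in range(2):
            if which == 0:
                prop = phi + 0.1 * np.random.standard_normal()
                if not (0.0 < prop < 1.0):
                    continue
                for t in range(T - 1):
                    phi_ad[0, t] = prop
                ll1 = _cjs_group_ll(2, marr, rel, phi_j, phi_ad, p, T)
                if math.log(np.random.random()) < ll1 - ll:
                    phi = prop
                    ll = ll1
                else:
                    for t in range(T - 1):
                        phi_ad[0, t] = phi
            else:
                prop = pdet + 0.1 * np.random.standard_normal()
                if not (0.0 < prop < 1.0):
                    continue
                for t in range(1, T):
                    p[2, t] = prop
                ll1 = _cjs_group_ll(2, marr, rel, phi_j, phi_ad, p, T)
                if math.log(np.random.random()) < ll1 - ll:
                    pdet = prop
                    ll = ll1
                else:
                    for t in range(1, T):
                        p[2, t] = pdet
        if it >= n_burnin and (it - n_burnin) % thin == thin - 1 and d < n_keep:
            out_phi[d] = phi
            out_p[d] = pdet
            d += 1
    return d
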
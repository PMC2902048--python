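"""Numba kernel for the hierarchical-shrinkage Gibbs sampler.

One systematic-scan sweep updates, in order: the intercept b0 (flat prior),
each effect b_k and its variance sigma_k^2 (N(0, sigma_k^2) prior with a
scaled inverse chi-square(-2*delta, 0) hyperprior, i.e. p(sigma_k^2)
proportional to (sigma_k^2)^(delta-1)), then the residual variance sigma^2
(scale-invariant 1/sigma^2 prior). The residual vector r = y - b0 - X b is
maintained incrementally and re-synchronised from scratch every
``RESYNC_EVERY`` sweeps to keep floating-point drift below tolerance.

The optional within-chain permutation reshuffles the phenotype vector after
the full sweep every ``reshuffle_every`` iterations, using a dedicated
xorshift64* stream so the permutation randomness is independent of the
sampler stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RESYNC_EVERY = 200

_XORSHIFT_MULT = np.uint64(0x2545F4914F6CDD1D)
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _xorshift_next(s):
    s ^= s >> np.uint64(12)
    s = (s ^ (s << np.uint64(25))) & _MASK64
    s ^= s >> np.uint64(27)
    return s


@njit(cache=True)
def _shuffle_phenotypes(y, r, s):
    """Fisher-Yates shuffle of y in place, keeping r = y - fitted consistent."""
    n = y.shape[0]
    for j in range(n - 1, 0, -1):
        s = _xorshift_next(s)
        u = (s * _XORSHIFT_MULT) & _MASK64
        i = int(u % np.uint64(j + 1))
        if i != j:
            fit_j = y[j] - r[j]
            fit_i = y[i] - r[i]
            y[i], y[j] = y[j], y[i]
            r[j] = y[j] - fit_j
            r[i] = y[i] - fit_i
    return s


@njit(cache=True)
def gibbs_chain(X, y, delta, burn_in, thin, n_draws, seed,
                reshuffle_every, perm_seed, effect_var_floor):
    """Run the full Gibbs chain and return retained draws.

    Parameters
    ----------
    X : (n, m) float64, Fortran-contiguous preferred
    y : (n,) float64 (copied; reshuffling never touches the caller's array)
    delta : hyperprior parameter in (0, 0.5)
    burn_in, thin, n_draws : chain schedule; total length burn_in + thin*n_draws
    seed : sampler stream seed (numba np.random)
    reshuffle_every : 0 disables within-chain permutation; h >= 1 reshuffles
        the phenotypes after every h-th full sweep
    perm_seed : seed of the xorshift64* permutation stream
    effect_var_floor : floor on b_k^2 when sampling sigma_k^2

    Returns
    -------
    effects : (n_draws, m) retained effect draws
    intercepts : (n_draws,) retained b0 draws
    sigma2s : (n_draws,) retained residual-variance draws
    resid_drift : max |incremental - recomputed| residual discrepancy seen at
        re-synchronisation points (bookkeeping diagnostic)
    """
    n, m = X.shape
    np.random.seed(seed)
    y = y.copy()

    xtx = np.empty(m)
    for k in range(m):
        acc = 0.0
        for j in range(n):
            acc += X[j, k] * X[j, k]
        xtx[k] = acc

    b0 = y.mean()
    b = np.zeros(m)
    sig2k = np.ones(m)
    sig2 = y.var()
    if sig2 <= 0.0:
        sig2 = 1.0
    r = y - b0

    shape_k = 0.5 * (1.0 - 2.0 * delta)
    shape_e = 0.5 * n
    s = np.uint64(perm_seed) | np.uint64(1)
    if reshuffle_every > 0:
        # the null chain runs on permuted data from iteration 1, so h = L
        # (one effective permutation) matches a single between-chain run
        s = _shuffle_phenotypes(y, r, s)

    total = burn_in + thin * n_draws
    effects = np.empty((n_draws, m))
    intercepts = np.empty(n_draws)
    sigma2s = np.empty(n_draws)
    kept = 0
    resid_drift = 0.0

    for it in range(1, total + 1):
        # --- intercept, flat prior: N(mean(y - Xb), sig2/n)
        rbar = 0.0
        for j in range(n):
            rbar += r[j]
        rbar /= n
        b0_new = (rbar + b0) + np.sqrt(sig2 / n) * np.random.standard_normal()
        d0 = b0_new - b0
        for j in range(n):
            r[j] -= d0
        b0 = b0_new

        # --- effects and their variances, locus order
        for k in range(m):
            bk = b[k]
            xtr = xtx[k] * bk
            for j in range(n):
                xtr += X[j, k] * r[j]
            v = sig2 / (xtx[k] + sig2 / sig2k[k])
            mu = v * xtr / sig2
            bk_new = mu + np.sqrt(v) * np.random.standard_normal()
            d = bk_new - bk
            if d != 0.0:
                for j in range(n):
                    r[j] -= X[j, k] * d
            b[k] = bk_new

            b2 = bk_new * bk_new
            if b2 < effect_var_floor:
                b2 = effect_var_floor
            g = np.random.gamma(shape_k, 1.0)
            sig2k[k] = 0.5 * b2 / g

        # --- residual variance, 1/sigma^2 prior: Inv-Gamma(n/2, SSE/2)
        sse = 0.0
        for j in range(n):
            sse += r[j] * r[j]
        g = np.random.gamma(shape_e, 1.0)
        sig2 = 0.5 * sse / g

        # --- within-chain permutation after the full sweep
        if reshuffle_every > 0 and it % reshuffle_every == 0:
            s = _shuffle_phenotypes(y, r, s)

        # --- periodic residual re-synchronisation
        if it % RESYNC_EVERY == 0:
            for j in range(n):
                acc = y[j] - b0
                for k in range(m):
                    acc -= X[j, k] * b[k]
                diff = abs(acc - r[j])
                if diff > resid_drift:
                    resid_drift = diff
                r[j] = acc

        if it > burn_in and (it - burn_in) % thin == 0:
            effects[kept, :] = b
            intercepts[kept] = b0
            sigma2s[kept] = sig2
            kept += 1

    return effects, intercepts, sigma2s, resid_drift
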
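"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np

from shrinkqtl import genotype_transition, recomb_fraction
from shrinkqtl.genmap import MISSING, get_design


def exhaustive_posterior(calls_row, gmap, cross, map_function="haldane"):
    """Marginal genotype posteriors by explicit summation over all paths."""
    cross = get_design(cross)
    S = cross.n_states
    out = np.zeros((gmap.n_loci, S))
    for _, idx in gmap.chromosome_slices():
        pos = gmap.positions[idx]
        trans = [
            genotype_transition(cross, recomb_fraction(pos[i + 1] - pos[i], map_function))
            for i in range(len(idx) - 1)
        ]
        L = len(idx)
        marg = np.zeros((L, S))
        total = 0.0
        for path in itertools.product(range(S), repeat=L):
            p = cross.frequencies[path[0]]
            ok = True
            for i in range(L):
                c = calls_row[idx[i]]
                if c != MISSING and c != path[i]:
                    ok = False
                    break
                if i > 0:
                    p *= trans[i - 1][path[i - 1], path[i]]
            if not ok:
                continue
            total += p
            for i in range(L):
                marg[i, path[i]] += p
        out[idx, :] = marg / total
    return out


def ridge_posterior(X, y, sigma_k2, sigma2):
    """Closed-form posterior of (b0, b) with fixed variances.

    Flat prior on b0, independent N(0, sigma_k2[k]) priors on b:
    precision A = W'W/sigma2 + diag(0, 1/sigma_k2), mean = A^{-1} W'y/sigma2.
    """
    n, m = X.shape
    W = np.column_stack([np.ones(n), X])
    prior_prec = np.diag(np.concatenate([[0.0], 1.0 / np.asarray(sigma_k2, float)]))
    A = W.T @ W / sigma2 + prior_prec
    cov = np.linalg.inv(A)
    mean = cov @ (W.T @ y) / sigma2
    return mean, cov
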
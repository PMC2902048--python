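"""Bayesian shrinkage regression of a trait on genome-wide marker scores.

The model is y_j = b0 + sum_k X_jk b_k + e_j with e_j ~ N(0, sigma^2) and a
hierarchical shrinkage prior on each marker effect:

    b_k | sigma_k^2 ~ N(0, sigma_k^2),
    sigma_k^2 ~ scaled-Inv-chi^2(-2*delta, 0)  (density prop. to (sigma_k^2)^(delta-1)),

with 0 < delta < 0.5 so the posterior of sigma_k^2 is proper. Small effects
are shrunk towards zero (their posterior is zero-inflated) while large
effects are nearly unpenalised, which lets all markers enter one model.

All full conditionals are standard conjugate forms; they are exposed both as
plain functions operating on a :class:`ChainState` (useful for testing and
as documentation of the sweep) and as a numba kernel used by
:class:`BayesianShrinkageRegressor.fit` for full-length chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._gibbs import gibbs_chain

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "ChainState",
    "PosteriorDraws",
    "initial_state",
    "update_intercept",
    "update_effect",
    "update_effect_variance",
    "update_residual_variance",
    "run_chain",
    "posterior_summaries",
    "BayesianShrinkageRegressor",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the shrinkage prior.

    ``delta`` parameterises the proper effect-variance prior
    scaled-Inv-chi^2(-2*delta, 0); delta -> 0 approaches the improper
    Jeffreys-type 1/sigma_k^2 prior. The residual variance carries the
    scale-invariant 1/sigma^2 prior.
    """

    delta: float = 0.05
    effect_var_floor: float = 1e-12

    def __post_init__(self):
        if not (0.0 < self.delta < 0.5):
            raise ValueError(f"delta must lie in (0, 0.5); got {self.delta}")
        if self.effect_var_floor <= 0:
            raise ValueError("effect_var_floor must be positive")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule: total length = burn_in + thin * n_draws."""

    burn_in: int = 1000
    thin: int = 10
    n_draws: int = 5000
    seed: int = 0

    def __post_init__(self):
        if min(self.burn_in, self.thin, self.n_draws) < 1:
            raise ValueError("burn_in, thin and n_draws must be positive")

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.thin * self.n_draws


@dataclass
class ChainState:
    """Current Gibbs state; ``residual`` is maintained as y - b0 - X b."""

    b0: float
    b: np.ndarray
    sigma_k2: np.ndarray
    sigma2: float
    residual: np.ndarray


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained draws of all model parameters plus chain metadata."""

    effects: np.ndarray  # (n_draws, m)
    intercepts: np.ndarray
    sigma2s: np.ndarray
    config: ChainConfig
    prior: PriorSpec
    resid_drift: float = 0.0
    locus_names: tuple = field(default=())

    @property
    def n_draws(self) -> int:
        return self.effects.shape[0]

    @property
    def n_loci(self) -> int:
        return self.effects.shape[1]


# ---------------------------------------------------------------------------
# full-conditional updates (reference implementation)
# ---------------------------------------------------------------------------

def initial_state(X, y) -> ChainState:
    """Start at b0 = mean(y), b = 0, sigma_k^2 = 1, sigma^2 = var(y)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    b0 = float(np.mean(y))
    sigma2 = float(np.var(y)) or 1.0
    return ChainState(
        b0=b0,
        b=np.zeros(X.shape[1]),
        sigma_k2=np.ones(X.shape[1]),
        sigma2=sigma2,
        residual=y - b0,
    )


def update_intercept(state: ChainState, y, rng) -> ChainState:
    """Draw b0 | rest ~ N(mean(y - Xb), sigma^2 / n) under a flat prior."""
    n = len(y)
    mean = float(np.mean(state.residual)) + state.b0
    b0_new = rng.normal(mean, np.sqrt(state.sigma2 / n))
    state.residual -= b0_new - state.b0
    state.b0 = b0_new
    return state


def update_effect(k: int, state: ChainState, X_k, rng) -> ChainState:
    """Draw b_k | rest from its conjugate normal conditional.

    v_k = sigma^2 / (X_k'X_k + sigma^2/sigma_k^2), mean = v_k X_k'r_k/sigma^2
    with r_k the residual after removing every effect but b_k. An all-zero
    column reduces to a draw from the N(0, sigma_k^2) prior.
    """
    X_k = np.asarray(X_k, float)
    xtx = float(X_k @ X_k)
    xtr = float(X_k @ state.residual) + xtx * state.b[k]
    v = state.sigma2 / (xtx + state.sigma2 / state.sigma_k2[k])
    mu = v * xtr / state.sigma2
    b_new = rng.normal(mu, np.sqrt(v))
    state.residual -= X_k * (b_new - state.b[k])
    state.b[k] = b_new
    return state


def update_effect_variance(b_k: float, prior: PriorSpec, rng) -> float:
    """Draw sigma_k^2 | b_k ~ scaled-Inv-chi^2(1 - 2*delta, b_k^2/(1 - 2*delta)).

    Equivalent inverse-gamma form: shape (1 - 2*delta)/2, rate b_k^2/2,
    sampled through the gamma family (shape < 1 is valid). b_k^2 is floored
    to avoid the absorbing state at exactly zero.
    """
    b2 = max(b_k * b_k, prior.effect_var_floor)
    shape = 0.5 * (1.0 - 2.0 * prior.delta)
    g = rng.gamma(shape, 1.0)
    return 0.5 * b2 / g


def update_residual_variance(state: ChainState, rng) -> float:
    """Draw sigma^2 | rest ~ Inv-Gamma(n/2, SSE/2) under the 1/sigma^2 prior."""
    n = len(state.residual)
    sse = float(state.residual @ state.residual)
    g = rng.gamma(0.5 * n, 1.0)
    return 0.5 * sse / g


def sweep(state: ChainState, X, y, prior: PriorSpec, rng) -> ChainState:
    """One systematic-scan sweep over (b0, each (b_k, sigma_k^2), sigma^2)."""
    state = update_intercept(state, y, rng)
    for k in range(X.shape[1]):
        state = update_effect(k, state, X[:, k], rng)
        state.sigma_k2[k] = update_effect_variance(state.b[k], prior, rng)
    state.sigma2 = update_residual_variance(state, rng)
    return state


# ---------------------------------------------------------------------------
# full chains (numba kernel)
# ---------------------------------------------------------------------------

def run_chain(X, y, prior: PriorSpec | None = None, config: ChainConfig | None = None,
              reshuffle_every: int = 0, permutation_seed: int | None = None,
              locus_names=()) -> PosteriorDraws:
    """Run the Gibbs sampler and return retained posterior draws.

    ``reshuffle_every=h`` (h >= 1) permutes the phenotypes after every h-th
    full sweep — the within-chain permutation used to build empirical null
    distributions; the permutation stream is seeded by ``permutation_seed``
    independently of the sampler stream.
    """
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError(f"X {X.shape} and y ({len(y)},) are not conformable")
    n, m = X.shape
    if n < 2 or m < 1:
        raise ValueError("need at least 2 individuals and 1 locus")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("X and y must not contain missing values")
    if permutation_seed is None:
        permutation_seed = config.seed + 777_767
    effects, intercepts, sigma2s, drift = gibbs_chain(
        np.asfortranarray(X),
        y,
        float(prior.delta),
        int(config.burn_in),
        int(config.thin),
        int(config.n_draws),
        int(config.seed) % (2**32),
        int(reshuffle_every),
        np.uint64(permutation_seed % (2**64)),
        float(prior.effect_var_floor),
    )
    return PosteriorDraws(
        effects=effects,
        intercepts=intercepts,
        sigma2s=sigma2s,
        config=config,
        prior=prior,
        resid_drift=float(drift),
        locus_names=tuple(locus_names),
    )


def posterior_summaries(draws: PosteriorDraws, alpha: float = 0.05) -> pd.DataFrame:
    """Per-locus posterior mean, sd and equal-tail credible interval.

    The interval is the empirical (alpha/2, 1 - alpha/2) percentile range of
    the retained draws.
    """
    if draws.n_draws < 2:
        raise ValueError("need at least 2 retained draws")
    eff = draws.effects
    lo, hi = np.quantile(eff, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    out = pd.DataFrame(
        {
            "post_mean": eff.mean(axis=0),
            "post_sd": eff.std(axis=0, ddof=1),
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )
    if draws.locus_names:
        out.insert(0, "locus", list(draws.locus_names))
    return out


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class BayesianShrinkageRegressor(RegressorMixin, BaseEstimator):
    """Whole-genome shrinkage regression fitted by Gibbs sampling.

    Fits y = b0 + X b + e with locus-specific shrinkage priors so that all
    markers can be included in a single model. ``coef_`` holds the posterior
    mean effects (the shrinkage estimates) and ``predict`` returns the
    estimated total genetic value b0 + X b.

    Parameters
    ----------
    delta : float in (0, 0.5)
        Effect-variance hyperprior parameter; smaller values shrink harder.
    burn_in, thin, n_draws : int
        Chain schedule; total length is burn_in + thin * n_draws.
    random_state : int
        Sampler seed (the estimator is deterministic given the seed).
    effect_var_floor : float
        Floor on b_k^2 when sampling sigma_k^2.

    Attributes
    ----------
    intercept_ : float — posterior mean of b0.
    coef_ : (m,) posterior mean marker effects.
    sigma2_ : float — posterior mean residual variance.
    draws_ : PosteriorDraws — all retained draws.
    n_iter_ : int — total Gibbs iterations executed.
    """

    def __init__(self, delta: float = 0.05, burn_in: int = 1000, thin: int = 10,
                 n_draws: int = 5000, random_state: int = 0,
                 effect_var_floor: float = 1e-12):
        self.delta = delta
        self.burn_in = burn_in
        self.thin = thin
        self.n_draws = n_draws
        self.random_state = random_state
        self.effect_var_floor = effect_var_floor

    def _config(self) -> ChainConfig:
        return ChainConfig(
            burn_in=self.burn_in, thin=self.thin, n_draws=self.n_draws,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        prior = PriorSpec(delta=self.delta, effect_var_floor=self.effect_var_floor)
        self.draws_ = run_chain(X, y, prior, self._config())
        self.intercept_ = float(self.draws_.intercepts.mean())
        self.coef_ = self.draws_.effects.mean(axis=0)
        self.sigma2_ = float(self.draws_.sigma2s.mean())
        self.n_iter_ = self._config().total_iterations
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    def credible_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        """Equal-tail posterior intervals of the marker effects."""
        check_is_fitted(self, "draws_")
        return posterior_summaries(self.draws_, alpha=alpha)
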
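"""Empirical genome-wide significance thresholds from phenotype permutation.

Permuting the phenotype vector breaks the genotype-phenotype link, so the
shrinkage estimates obtained from permuted data sample the null distribution
of each marker effect. Two strategies are provided:

* between-chain — run an independent full chain on each permuted dataset and
  record one observation per effect per permutation (default: the posterior
  mean, matching the narrower thresholds this strategy produces);
* within-chain — run a single chain in which the phenotypes are reshuffled
  after every h-th sweep; the retained draws themselves form the null
  sample. h = L (never reshuffling after the initial permutation) recovers a
  single between-chain run; h = 1 (default) reshuffles every sweep and gives
  the smoothest percentile profiles.

Per-locus critical values are the empirical (alpha/2, 1 - alpha/2)
percentiles of the null sample; an effect estimate strictly outside its
locus interval is declared significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import ChainConfig, PosteriorDraws, PriorSpec, run_chain

__all__ = [
    "ThresholdProfile",
    "permute_phenotypes",
    "run_within_chain_null",
    "run_between_chain_null",
    "thresholds",
    "declare_significant",
]


@dataclass(frozen=True)
class ThresholdProfile:
    """Per-locus (lower, upper) empirical critical values at each alpha."""

    alphas: tuple
    lower: np.ndarray  # (n_alphas, m)
    upper: np.ndarray  # (n_alphas, m)
    mode: str = "within"
    h: int | None = None
    n_null: int = 0
    locus_names: tuple = field(default=())

    def at(self, alpha: float):
        """Return (lower, upper) arrays for one alpha level."""
        for i, a in enumerate(self.alphas):
            if np.isclose(a, alpha):
                return self.lower[i], self.upper[i]
        raise KeyError(f"alpha {alpha} not among computed levels {self.alphas}")

    def to_frame(self) -> pd.DataFrame:
        data = {}
        if self.locus_names:
            data["locus"] = list(self.locus_names)
        for i, a in enumerate(self.alphas):
            data[f"lower_{a:g}"] = self.lower[i]
            data[f"upper_{a:g}"] = self.upper[i]
        return pd.DataFrame(data)


def permute_phenotypes(y, rng) -> np.ndarray:
    """Return a uniform random permutation of the phenotype vector."""
    y = np.asarray(y)
    if len(y) < 2:
        raise ValueError("need at least 2 phenotypes to permute")
    return rng.permutation(y)


def run_within_chain_null(X, y, prior: PriorSpec | None = None,
                          config: ChainConfig | None = None, h: int = 1,
                          permutation_seed: int | None = None) -> PosteriorDraws:
    """Null-distribution chain with phenotypes reshuffled every h-th sweep.

    Identical to the main chain except for the periodic reshuffle (after the
    full sweep, counting from iteration 1); the retained draws are the
    per-locus empirical null sample. The permutation stream is independent
    of the sampler stream.
    """
    if h < 1:
        raise ValueError("reshuffle interval h must be >= 1")
    return run_chain(
        X, y, prior, config, reshuffle_every=h, permutation_seed=permutation_seed
    )


def run_between_chain_null(X, y, prior: PriorSpec | None = None,
                           config: ChainConfig | None = None,
                           n_permutations: int = 1000, seed: int = 0,
                           record: str = "mean") -> np.ndarray:
    """Independent-chains permutation null: one observation per permutation.

    For each permutation an independent full chain is run on freshly
    permuted phenotypes; per effect, ``record="mean"`` stores the posterior
    mean (default) and ``record="last"`` the final retained draw. Returns an
    (n_permutations, m) null sample.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if record not in ("mean", "last"):
        raise ValueError("record must be 'mean' or 'last'")
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    perm_rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_permutations):
        y_star = permute_phenotypes(y, perm_rng)
        cfg = ChainConfig(config.burn_in, config.thin, config.n_draws,
                          seed=config.seed + p + 1)
        draws = run_chain(X, y_star, prior, cfg)
        if record == "mean":
            rows.append(draws.effects.mean(axis=0))
        else:
            rows.append(draws.effects[-1])
    return np.vstack(rows)


def thresholds(null_sample, alphas=(0.05,), mode: str = "within",
               h: int | None = None, locus_names=()) -> ThresholdProfile:
    """Empirical per-locus critical values from a null sample.

    ``null_sample`` is (n_null, m): within-chain retained draws or
    between-chain recorded observations. Percentiles use linear
    interpolation between order statistics.
    """
    null_sample = np.asarray(null_sample, float)
    if null_sample.ndim != 2:
        raise ValueError("null sample must be 2-dimensional (draws x loci)")
    if null_sample.shape[0] < 2:
        raise ValueError("need at least 2 null draws per locus")
    alphas = tuple(float(a) for a in (alphas if np.iterable(alphas) else [alphas]))
    for a in alphas:
        if not (0.0 < a < 1.0):
            raise ValueError(f"alpha must be in (0, 1); got {a}")
    lower = np.empty((len(alphas), null_sample.shape[1]))
    upper = np.empty_like(lower)
    for i, a in enumerate(alphas):
        lower[i] = np.quantile(null_sample, a / 2.0, axis=0)
        upper[i] = np.quantile(null_sample, 1.0 - a / 2.0, axis=0)
    return ThresholdProfile(
        alphas=alphas, lower=lower, upper=upper, mode=mode, h=h,
        n_null=null_sample.shape[0], locus_names=tuple(locus_names),
    )


def declare_significant(estimates, profile: ThresholdProfile, alpha: float) -> pd.DataFrame:
    """Flag loci whose estimate falls strictly outside the critical interval.

    ``estimates`` may be a vector of per-locus estimates (posterior means)
    or a summaries DataFrame with a ``post_mean`` column. Boundary values
    are not significant (strict inequality).
    """
    if isinstance(estimates, pd.DataFrame):
        est = estimates["post_mean"].to_numpy()
    else:
        est = np.asarray(estimates, float)
    lower, upper = profile.at(alpha)
    if est.shape != lower.shape:
        raise ValueError(
            f"estimates cover {est.shape[0]} loci but thresholds cover {lower.shape[0]}"
        )
    low = est < lower
    high = est > upper
    side = np.where(high, "high", np.where(low, "low", ""))
    out = pd.DataFrame(
        {
            "estimate": est,
            "lower": lower,
            "upper": upper,
            "significant": low | high,
            "side": side,
        }
    )
    if profile.locus_names:
        out.insert(0, "locus", list(profile.locus_names))
    return out
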
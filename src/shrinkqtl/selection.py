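"""Cross-validated choice of the inclusion stringency for genome selection.

Genome selection predicts an individual's total genetic value from marker
effects estimated on a training sample. Including every tiny estimated
effect can add noise; masking effects that fail an empirical significance
threshold at level gamma trades bias for variance. The squared prediction
error over k-fold cross-validation,

    Delta_s(gamma) = mean over fold s of (y - b0_hat - X b_hat(gamma))^2,
    PE(gamma) = mean over folds of Delta_s(gamma),

is computed on a grid of gamma values; the gamma minimising PE is the
recommended inclusion criterion. gamma = 0 masks every effect (intercept-only
prediction, since a 0%-100% null interval contains every estimate) and
gamma = 1 includes all of them (the unmasked model).

Per fold, one shrinkage chain is fitted on the training 4/5 and one
within-chain permutation null chain provides the thresholds; the same null
sample yields the percentiles at every gamma in the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .permutation import declare_significant, run_within_chain_null, thresholds
from .regression import BayesianShrinkageRegressor, ChainConfig, PriorSpec, run_chain

__all__ = [
    "PEProfile",
    "kfold_partition",
    "masked_predict",
    "fold_prediction_error",
    "cv_pe_curve",
    "optimal_gamma",
]

DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class PEProfile:
    """Squared prediction error against inclusion stringency gamma."""

    gammas: tuple
    fold_errors: np.ndarray  # (n_folds, n_gammas)
    n_folds: int = field(default=5)

    @property
    def pe(self) -> np.ndarray:
        """PE(gamma): mean of the fold errors."""
        return self.fold_errors.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fold_errors.T,
            columns=[f"fold_{s + 1}" for s in range(self.fold_errors.shape[0])],
        )
        df.insert(0, "gamma", list(self.gammas))
        df["PE"] = self.pe
        return df


def kfold_partition(n: int, k: int, rng) -> np.ndarray:
    """Assign each of n individuals to one of k folds (sizes differ by <= 1)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    seed = int(rng.integers(2**31)) if isinstance(rng, np.random.Generator) else int(rng)
    assignment = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(kf.split(np.empty((n, 1)))):
        assignment[test_idx] = fold
    return assignment


def masked_predict(X_test, b0_hat: float, b_hat, significant) -> np.ndarray:
    """Predict phenotypes using only effects flagged significant.

    ``significant`` is a boolean mask per locus (or a calls DataFrame with a
    ``significant`` column); masked effects are treated as zero.
    """
    if isinstance(significant, pd.DataFrame):
        significant = significant["significant"].to_numpy()
    mask = np.asarray(significant, bool)
    b = np.where(mask, np.asarray(b_hat, float), 0.0)
    return b0_hat + np.asarray(X_test, float) @ b


def fold_prediction_error(y_test, y_hat) -> float:
    """Mean squared prediction error over one held-out fold."""
    y_test = np.asarray(y_test, float)
    y_hat = np.asarray(y_hat, float)
    if y_test.shape != y_hat.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if y_test.size == 0:
        raise ValueError("empty fold")
    return float(np.mean((y_test - y_hat) ** 2))


def _mask_at_gamma(est, profile, gamma: float) -> np.ndarray:
    """Inclusion mask at stringency gamma (0: none pass, 1: all pass)."""
    if gamma <= 0.0:
        return np.zeros(len(est), dtype=bool)
    if gamma >= 1.0:
        return np.ones(len(est), dtype=bool)
    calls = declare_significant(est, profile, gamma)
    return calls["significant"].to_numpy()


def cv_pe_curve(X, y, n_folds: int = 5, gamma_grid=DEFAULT_GAMMA_GRID,
                prior: PriorSpec | None = None, config: ChainConfig | None = None,
                h: int = 1, seed: int = 0) -> PEProfile:
    """K-fold cross-validated PE(gamma) profile.

    For each fold the shrinkage chain and a within-chain permutation null are
    fitted on the training portion; thresholds at every gamma on the grid
    come from that single null sample. Missing phenotypes (NaN) are replaced
    by the sample mean before partitioning.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).copy()
    if np.isnan(y).any():
        y[np.isnan(y)] = np.nanmean(y)
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    gammas = tuple(float(g) for g in gamma_grid)
    interior = [g for g in gammas if 0.0 < g < 1.0]
    folds = kfold_partition(len(y), n_folds, np.random.default_rng(seed))
    fold_errors = np.empty((n_folds, len(gammas)))
    for s in range(n_folds):
        test = folds == s
        train = ~test
        cfg = ChainConfig(config.burn_in, config.thin, config.n_draws,
                          seed=config.seed + 1000 * (s + 1))
        draws = run_chain(X[train], y[train], prior, cfg)
        b0_hat = float(draws.intercepts.mean())
        b_hat = draws.effects.mean(axis=0)
        null = run_within_chain_null(
            X[train], y[train], prior, cfg, h=h,
            permutation_seed=cfg.seed + 5_000_017,
        )
        profile = thresholds(null.effects, alphas=interior) if interior else None
        for gi, g in enumerate(gammas):
            mask = _mask_at_gamma(b_hat, profile, g) if 0.0 < g < 1.0 else _mask_at_gamma(b_hat, None, g)
            y_hat = masked_predict(X[test], b0_hat, b_hat, mask)
            fold_errors[s, gi] = fold_prediction_error(y[test], y_hat)
    return PEProfile(gammas=gammas, fold_errors=fold_errors, n_folds=n_folds)


def optimal_gamma(profile: PEProfile) -> float:
    """Grid gamma with minimal PE; ties break toward the larger (more
    inclusive) gamma, reflecting that including all effects is a robust
    fallback."""
    pe = profile.pe
    best = pe.min()
    idx = np.flatnonzero(np.isclose(pe, best))
    return float(profile.gammas[idx[-1]])
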
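"""Replicated-simulation power and false-positive-rate study.

Each replicate simulates a fresh cross, fits the shrinkage chain on the
original data and a within-chain permutation null chain, forms per-locus
empirical thresholds and declares significance. A true QTL counts as
detected when any marker in its detection window — the markers within 10 cM
of the QTL (a 20 cM range, i.e. the marker triplet covering it, truncated
at chromosome ends) — is significant. Markers belonging to no window are
"false" loci; a significant call there is a false positive. Power and
per-locus false positive rates are the corresponding proportions across
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .permutation import declare_significant, run_within_chain_null, thresholds
from .regression import ChainConfig, PriorSpec, run_chain
from .simulate import TraitModel, simulate_cross

__all__ = [
    "PowerResult",
    "FPRResult",
    "detection_window",
    "reserved_and_false_loci",
    "run_replication_study",
]

WINDOW_CM = 10.0  # half-width of the detection window around a true QTL


@dataclass(frozen=True)
class PowerResult:
    """Per-QTL detection counts and power at each alpha level."""

    alphas: tuple
    detections: np.ndarray  # (n_alphas, n_qtl) counts
    n_replicates: int

    @property
    def power(self) -> np.ndarray:
        return self.detections / self.n_replicates

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"qtl": np.arange(1, self.detections.shape[1] + 1)})
        for i, a in enumerate(self.alphas):
            df[f"power_{a:g}"] = self.power[i]
        return df


@dataclass(frozen=True)
class FPRResult:
    """Per-false-locus false-positive counts and rates at each alpha level."""

    alphas: tuple
    false_locus_indices: np.ndarray
    counts: np.ndarray  # (n_alphas, n_false)
    n_replicates: int

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.n_replicates

    def average_rate(self, alpha: float) -> float:
        for i, a in enumerate(self.alphas):
            if np.isclose(a, alpha):
                return float(self.rates[i].mean())
        raise KeyError(f"alpha {alpha} not among computed levels {self.alphas}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"locus_index": self.false_locus_indices + 1})
        for i, a in enumerate(self.alphas):
            df[f"fpr_{a:g}"] = self.rates[i]
        return df


def detection_window(chromosome: str, position: float, gmap: GeneticMap,
                     window_cM: float = WINDOW_CM) -> np.ndarray:
    """Indices of map markers within ``window_cM`` of a QTL position.

    For a QTL sitting on a marker of an evenly spaced map with interval equal
    to ``window_cM`` this is the covering marker triplet (marker plus one
    flank each side), truncated at chromosome ends.
    """
    chroms = np.asarray(gmap.chromosomes)
    sel = (chroms == str(chromosome)) & (
        np.abs(gmap.positions - position) <= window_cM + 1e-9
    )
    return np.flatnonzero(sel & ~gmap.is_pseudomarker)


def reserved_and_false_loci(model: TraitModel, gmap: GeneticMap):
    """Partition map markers into QTL-window (reserved) and false loci.

    Reserved loci are the union of the detection windows of all true QTL;
    overlapping windows of closely linked QTL are counted once. Every other
    marker is a potential false positive.
    """
    reserved = set()
    for q in model.qtls:
        reserved.update(detection_window(q.chromosome, q.position, gmap).tolist())
    all_idx = set(gmap.marker_indices().tolist())
    false = np.array(sorted(all_idx - reserved), dtype=int)
    return np.array(sorted(reserved), dtype=int), false


def run_replication_study(model: TraitModel, gmap: GeneticMap, cross="f2",
                          n_replicates: int = 100, sample_size: int = 500,
                          alphas=(0.05, 0.10), prior: PriorSpec | None = None,
                          config: ChainConfig | None = None, h: int = 1,
                          map_function: str = "haldane", base_seed: int = 0,
                          progress=None):
    """Replicate the simulate-fit-test pipeline and aggregate power and FPR.

    Replicate seeds are ``base_seed + replicate`` so any execution order (or
    a resumed run) yields identical aggregates. Two chains run per
    replicate: the estimation chain and the within-chain permutation null.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    alphas = tuple(float(a) for a in alphas)
    windows = [detection_window(q.chromosome, q.position, gmap) for q in model.qtls]
    _, false_idx = reserved_and_false_loci(model, gmap)
    det = np.zeros((len(alphas), len(model.qtls)), dtype=int)
    fp = np.zeros((len(alphas), len(false_idx)), dtype=int)
    for rep in range(n_replicates):
        seed = base_seed + rep
        X, y = simulate_cross(gmap, model, cross, sample_size, map_function, seed=seed)
        cfg = ChainConfig(config.burn_in, config.thin, config.n_draws,
                          seed=config.seed + 10_000 * (rep + 1))
        draws = run_chain(X, y, prior, cfg)
        est = draws.effects.mean(axis=0)
        null = run_within_chain_null(
            X, y, prior, cfg, h=h, permutation_seed=cfg.seed + 5_000_017
        )
        profile = thresholds(null.effects, alphas=alphas)
        for ai, a in enumerate(alphas):
            calls = declare_significant(est, profile, a)["significant"].to_numpy()
            for qi, win in enumerate(windows):
                if calls[win].any():
                    det[ai, qi] += 1
            fp[ai] += calls[false_idx]
        if progress is not None:
            progress(rep + 1, n_replicates)
    power = PowerResult(alphas=alphas, detections=det, n_replicates=n_replicates)
    fpr = FPRResult(alphas=alphas, false_locus_indices=false_idx, counts=fp,
                    n_replicates=n_replicates)
    return power, fpr
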
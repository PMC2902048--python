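"""Genetic maps, cross designs, map functions and multipoint genotype probabilities.

A :class:`GeneticMap` is an ordered list of loci (markers and pseudomarkers)
with chromosome assignments and sex-averaged positions in centiMorgans.
Genotypes along a chromosome are modelled as a Markov chain whose transition
matrices depend on the inter-locus recombination fraction; the multipoint
(forward-backward) algorithm turns sparse, possibly missing marker calls into
conditional genotype probabilities at every locus, including untyped
pseudomarkers, which are then collapsed to the numeric codings used by the
regression model (F2: P(A1A1) - P(A2A2); two-state designs: P(state 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "CrossDesign",
    "F2",
    "BC",
    "DH",
    "RIL",
    "recomb_fraction",
    "genotype_transition",
    "insert_pseudomarkers",
    "conditional_genotype_probs",
    "code_genotypes",
]

MISSING = -1  # sentinel for an untyped genotype call


# ---------------------------------------------------------------------------
# cross designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossDesign:
    """An experimental cross design: genotype states, frequencies, codings.

    Parameters
    ----------
    kind : str
        One of ``"f2"``, ``"bc"``, ``"dh"``, ``"ril"``.
    states : tuple of str
        Ordered genotype labels (F2: A1A1, A1A2, A2A2; two-state designs:
        the two homozygous / parental-line states).
    frequencies : tuple of float
        Expected Mendelian genotype frequencies under no distortion.
    codes : tuple of float
        Numeric score for each state (F2: 1, 0, -1; two-state: 1, 0).
    """

    kind: str
    states: tuple = field(default=())
    frequencies: tuple = field(default=())
    codes: tuple = field(default=())

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise ValueError(
                f"genotype {label!r} is not a state of the {self.kind} design "
                f"(expected one of {self.states})"
            ) from None


F2 = CrossDesign("f2", ("A1A1", "A1A2", "A2A2"), (0.25, 0.5, 0.25), (1.0, 0.0, -1.0))
BC = CrossDesign("bc", ("A1A1", "A1A2"), (0.5, 0.5), (1.0, 0.0))
DH = CrossDesign("dh", ("A1A1", "A2A2"), (0.5, 0.5), (1.0, 0.0))
RIL = CrossDesign("ril", ("A1A1", "A2A2"), (0.5, 0.5), (1.0, 0.0))

_DESIGNS = {"f2": F2, "bc": BC, "dh": DH, "ril": RIL}


def get_design(kind) -> CrossDesign:
    """Resolve a design name or pass a :class:`CrossDesign` through."""
    if isinstance(kind, CrossDesign):
        return kind
    try:
        return _DESIGNS[str(kind).lower()]
    except KeyError:
        raise ValueError(f"unknown cross design {kind!r}; choose from {sorted(_DESIGNS)}") from None


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Ordered loci with chromosome, cM position and pseudomarker flag.

    Positions must be non-decreasing within each chromosome, names unique,
    positions non-negative. Chromosomes are kept in first-appearance order.
    """

    def __init__(self, loci, chromosomes, positions, is_pseudomarker=None):
        loci = list(loci)
        chromosomes = [str(c) for c in chromosomes]
        positions = np.asarray(positions, dtype=float)
        if not (len(loci) == len(chromosomes) == len(positions)):
            raise ValueError("loci, chromosomes and positions must have equal length")
        if len(loci) == 0:
            raise ValueError("a genetic map must contain at least one locus")
        if len(set(loci)) != len(loci):
            raise ValueError("locus names must be unique")
        if np.any(positions < 0):
            raise ValueError("cM positions must be non-negative")
        if is_pseudomarker is None:
            is_pseudomarker = np.zeros(len(loci), dtype=bool)
        else:
            is_pseudomarker = np.asarray(is_pseudomarker, dtype=bool)
        for chrom in dict.fromkeys(chromosomes):
            pos_c = positions[[c == chrom for c in chromosomes]]
            if np.any(np.diff(pos_c) < 0):
                raise ValueError(f"positions on chromosome {chrom} are not sorted")
        self.loci = loci
        self.chromosomes = chromosomes
        self.positions = positions
        self.is_pseudomarker = is_pseudomarker

    # -- basic interface ----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def __len__(self) -> int:
        return self.n_loci

    def chromosome_names(self):
        return list(dict.fromkeys(self.chromosomes))

    def chromosome_slices(self):
        """Yield ``(chrom, index array)`` pairs in map order."""
        chroms = np.asarray(self.chromosomes)
        for chrom in self.chromosome_names():
            yield chrom, np.flatnonzero(chroms == chrom)

    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_pseudomarker)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.loci,
                "chromosome": self.chromosomes,
                "position_cM": self.positions,
                "is_pseudomarker": self.is_pseudomarker,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        pseudo = df["is_pseudomarker"] if "is_pseudomarker" in df.columns else None
        return cls(df["locus"], df["chromosome"], df["position_cM"], pseudo)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, dtype={"chromosome": str})
        required = {"locus", "chromosome", "position_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"map file must have columns {sorted(required)}; got {list(df.columns)}")
        return cls.from_frame(df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneticMap({self.n_loci} loci on {len(self.chromosome_names())} "
            f"chromosome(s), {int(self.is_pseudomarker.sum())} pseudomarkers)"
        )


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def recomb_fraction(distance_cM, map_function: str = "haldane"):
    """Map a genetic distance in cM to a recombination fraction.

    Haldane (no interference): r = (1 - exp(-2d/100)) / 2.
    Kosambi: r = tanh(2d/100) / 2.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    if map_function == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif map_function == "kosambi":
        r = 0.5 * np.tanh(2.0 * d / 100.0)
    else:
        raise ValueError("map_function must be 'haldane' or 'kosambi'")
    return r if r.ndim else float(r)


def genotype_transition(cross, r: float) -> np.ndarray:
    """Markov transition matrix over genotype states for one marker interval.

    F2 genotypes are the unordered pair of two independent gamete chains,
    each recombining with probability ``r``. BC/DH transition directly with
    probability ``r``; selfed RILs use the expected (Haldane-Waddington)
    recombination 2r/(1+2r) between fixed lines.
    """
    cross = get_design(cross)
    if not (0.0 <= r <= 0.5):
        raise ValueError(f"recombination fraction must be in [0, 0.5]; got {r}")
    if cross.kind == "f2":
        s, t = 1.0 - r, r
        return np.array(
            [
                [s * s, 2 * s * t, t * t],
                [s * t, s * s + t * t, s * t],
                [t * t, 2 * s * t, s * s],
            ]
        )
    if cross.kind == "ril":
        r = 2.0 * r / (1.0 + 2.0 * r)
    return np.array([[1.0 - r, r], [r, 1.0 - r]])


# ---------------------------------------------------------------------------
# pseudomarkers
# ---------------------------------------------------------------------------

def insert_pseudomarkers(gmap: GeneticMap, step: float, tol: float = 1e-6) -> GeneticMap:
    """Insert pseudomarkers on a regular cM grid within each chromosome.

    The grid is anchored at the first locus of each chromosome and runs to its
    last locus; grid points within ``tol`` cM of an existing locus are skipped
    so typed markers are never duplicated. Original loci are preserved.
    """
    if step <= 0:
        raise ValueError("pseudomarker step must be positive")
    loci, chroms, positions, pseudo = [], [], [], []
    for chrom, idx in gmap.chromosome_slices():
        pos_c = gmap.positions[idx]
        entries = [
            (gmap.positions[i], gmap.loci[i], gmap.is_pseudomarker[i]) for i in idx
        ]
        start, stop = pos_c[0], pos_c[-1]
        g = start + step
        while g < stop - tol:
            if np.min(np.abs(pos_c - g)) > tol:
                entries.append((g, f"c{chrom}.loc{g:g}", True))
            g += step
        entries.sort(key=lambda e: e[0])
        for p, name, flag in entries:
            positions.append(p)
            loci.append(name)
            chroms.append(chrom)
            pseudo.append(flag)
    return GeneticMap(loci, chroms, positions, pseudo)


# ---------------------------------------------------------------------------
# multipoint conditional genotype probabilities
# ---------------------------------------------------------------------------

def _interval_transitions(gmap, idx, cross, map_function):
    """Transition matrices for the consecutive intervals of one chromosome."""
    pos = gmap.positions[idx]
    return [
        genotype_transition(cross, recomb_fraction(pos[i + 1] - pos[i], map_function))
        for i in range(len(idx) - 1)
    ]


def conditional_genotype_probs(calls, gmap: GeneticMap, cross, map_function: str = "haldane"):
    """Multipoint posterior genotype probabilities at every locus of the map.

    Parameters
    ----------
    calls : (n, n_loci) integer array
        Genotype state indices per individual and map locus; ``-1`` marks a
        missing call. Pseudomarker columns must be entirely missing. (Use
        :func:`calls_from_labels` to build this array from string labels.)
    gmap : GeneticMap
    cross : CrossDesign or str
    map_function : str

    Returns
    -------
    (n, n_loci, n_states) array
        Forward-backward posterior over the genotype chain of each
        chromosome; rows sum to one, typed loci carry a point mass.
    """
    cross = get_design(cross)
    calls = np.asarray(calls, dtype=int)
    if calls.ndim != 2 or calls.shape[1] != gmap.n_loci:
        raise ValueError(
            f"calls must be (n, {gmap.n_loci}); got {calls.shape}"
        )
    S = cross.n_states
    if calls.max(initial=-1) >= S:
        raise ValueError(
            f"genotype call index out of range for the {cross.kind} design ({S} states)"
        )
    n = calls.shape[0]
    init = np.asarray(cross.frequencies)
    out = np.empty((n, gmap.n_loci, S))
    for _, idx in gmap.chromosome_slices():
        trans = _interval_transitions(gmap, idx, cross, map_function)
        out[:, idx, :] = _forward_backward_chrom(calls[:, idx], init, trans, S)
    return out


def _forward_backward_chrom(calls, init, trans, S):
    """Scaled forward-backward for one chromosome, all individuals."""
    n, L = calls.shape
    post = np.empty((n, L, S))
    for j in range(n):
        # emission: point mass at a typed locus, all-ones when missing
        emit = np.ones((L, S))
        for i in range(L):
            c = calls[j, i]
            if c != MISSING:
                emit[i, :] = 0.0
                emit[i, c] = 1.0
        alpha = np.empty((L, S))
        scale = np.empty(L)
        a = init * emit[0]
        scale[0] = a.sum()
        if scale[0] == 0:
            raise ValueError("impossible genotype configuration (zero likelihood)")
        alpha[0] = a / scale[0]
        for i in range(1, L):
            a = (alpha[i - 1] @ trans[i - 1]) * emit[i]
            scale[i] = a.sum()
            if scale[i] == 0:
                raise ValueError("impossible genotype configuration (zero likelihood)")
            alpha[i] = a / scale[i]
        beta = np.empty((L, S))
        beta[L - 1] = 1.0
        for i in range(L - 2, -1, -1):
            beta[i] = trans[i] @ (emit[i + 1] * beta[i + 1]) / scale[i + 1]
        p = alpha * beta
        post[j] = p / p.sum(axis=1, keepdims=True)
    return post


def calls_from_labels(labels, cross, missing=("-", "", "NA", "nan")):
    """Convert an array/DataFrame of genotype labels to state-index calls."""
    cross = get_design(cross)
    arr = np.asarray(labels, dtype=object)
    out = np.empty(arr.shape, dtype=int)
    flat_in, flat_out = arr.ravel(), out.ravel()
    for i, v in enumerate(flat_in):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in missing:
            flat_out[i] = MISSING
        else:
            flat_out[i] = cross.state_index(str(v).strip())
    return out


def code_genotypes(probs, cross) -> np.ndarray:
    """Collapse genotype probabilities to the numeric regression coding.

    F2: X = P(A1A1) - P(A2A2), in [-1, 1]. Two-state designs:
    X = P(state 1), in [0, 1]. Accepts a (n, L, S) probability table or a
    (n, L) integer state array (converted to point masses).
    """
    cross = get_design(cross)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 2:  # state indices
        states = probs.astype(int)
        codes = np.asarray(cross.codes)
        return codes[states]
    if probs.shape[-1] != cross.n_states:
        raise ValueError("probability table state dimension does not match the design")
    if cross.kind == "f2":
        return probs[..., 0] - probs[..., 2]
    return probs[..., 0]
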
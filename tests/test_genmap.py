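"""Genetic map, map functions, transitions and multipoint genotype probabilities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shrinkqtl import (
    BC,
    DH,
    F2,
    RIL,
    GeneticMap,
    code_genotypes,
    conditional_genotype_probs,
    genotype_transition,
    insert_pseudomarkers,
    recomb_fraction,
)
from shrinkqtl.genmap import MISSING, get_design

from _oracles import exhaustive_posterior

ALL_DESIGNS = [F2, BC, DH, RIL]


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

class TestRecombFraction:
    @pytest.mark.parametrize("fn", ["haldane", "kosambi"])
    def test_limits(self, fn):
        assert recomb_fraction(0.0, fn) == 0.0
        assert recomb_fraction(1e6, fn) == pytest.approx(0.5, abs=1e-12)

    def test_haldane_closed_form_10cM(self):
        # (1 - e^{-0.2})/2, evaluated independently
        assert recomb_fraction(10.0, "haldane") == pytest.approx(0.090635, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            recomb_fraction(-1.0)

    @given(st.floats(min_value=0.01, max_value=500.0), st.floats(min_value=0.01, max_value=500.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, d1, d2):
        lo, hi = sorted([d1, d2])
        for fn in ("haldane", "kosambi"):
            r_lo, r_hi = recomb_fraction(lo, fn), recomb_fraction(hi, fn)
            assert 0.0 < r_lo <= r_hi < 0.5


class TestGenotypeTransition:
    def test_dh_no_recombination_is_identity(self):
        np.testing.assert_allclose(genotype_transition(DH, 0.0), np.eye(2))

    def test_dh_direct_probability(self):
        np.testing.assert_allclose(
            genotype_transition(DH, 0.2), [[0.8, 0.2], [0.2, 0.8]]
        )

    def test_f2_matches_two_gamete_chain_enumeration(self):
        # brute force: enumerate ordered gamete pairs, each chain recombining
        # with probability r, collapse to unordered genotype counts
        r = 0.1
        T = np.zeros((3, 3))
        for a0, b0 in itertools.product([0, 1], repeat=2):
            start = a0 + b0
            p_start = 0.25  # each allele equally likely; ordered pairs
            for a1, b1 in itertools.product([0, 1], repeat=2):
                p = (r if a1 != a0 else 1 - r) * (r if b1 != b0 else 1 - r)
                T[start, a1 + b1] += p_start * p
        # rows of T currently weighted by ordered-state frequency; normalize per
        # collapsed start state (het has two ordered versions)
        T[0] /= 0.25
        T[1] /= 0.5
        T[2] /= 0.25
        np.testing.assert_allclose(genotype_transition(F2, r), T, atol=1e-14)

    @pytest.mark.parametrize("cross", ALL_DESIGNS)
    @pytest.mark.parametrize("r", [0.0, 0.05, 0.25, 0.5])
    def test_rows_sum_to_one_and_symmetry(self, cross, r):
        T = genotype_transition(cross, r)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-14)
        # relabeling A1 <-> A2 reverses the state order
        np.testing.assert_allclose(T, T[::-1, ::-1], atol=1e-14)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            genotype_transition(DH, 0.6)

    def test_stationarity_of_mendelian_frequencies(self):
        for cross in ALL_DESIGNS:
            freqs = np.asarray(cross.frequencies)
            T = genotype_transition(cross, 0.13)
            np.testing.assert_allclose(freqs @ T, freqs, atol=1e-12)


# ---------------------------------------------------------------------------
# map container and pseudomarkers
# ---------------------------------------------------------------------------

class TestGeneticMap:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneticMap(["a", "a"], ["1", "1"], [0, 1])  # duplicate name
        with pytest.raises(ValueError):
            GeneticMap(["a", "b"], ["1", "1"], [5, 1])  # unsorted
        with pytest.raises(ValueError):
            GeneticMap(["a"], ["1"], [-2])  # negative position
        with pytest.raises(ValueError):
            GeneticMap([], [], [])

    def test_csv_round_trip(self, two_chrom_map, tmp_path):
        path = tmp_path / "map.csv"
        two_chrom_map.to_csv(path)
        back = GeneticMap.from_csv(path)
        assert back.loci == two_chrom_map.loci
        np.testing.assert_allclose(back.positions, two_chrom_map.positions)
        assert back.chromosomes == two_chrom_map.chromosomes


class TestInsertPseudomarkers:
    def test_midpoint_inserted(self):
        gmap = GeneticMap(["a", "b"], ["1", "1"], [0.0, 4.0])
        out = insert_pseudomarkers(gmap, 2.0)
        assert out.n_loci == 3
        np.testing.assert_allclose(out.positions, [0.0, 2.0, 4.0])
        assert list(out.is_pseudomarker) == [False, True, False]
        assert out.loci[0] == "a" and out.loci[2] == "b"

    def test_grid_point_on_marker_skipped(self):
        gmap = GeneticMap(["a", "b"], ["1", "1"], [0.0, 2.0])
        out = insert_pseudomarkers(gmap, 2.0)
        assert out.n_loci == 2

    def test_step_longer_than_chromosome(self):
        gmap = GeneticMap(["a", "b"], ["1", "1"], [0.0, 4.0])
        out = insert_pseudomarkers(gmap, 50.0)
        assert out.n_loci == 2

    def test_invalid_step(self, small_map):
        with pytest.raises(ValueError):
            insert_pseudomarkers(small_map, 0.0)

    def test_positions_sorted_and_markers_preserved(self, two_chrom_map):
        out = insert_pseudomarkers(two_chrom_map, 2.0)
        for _, idx in out.chromosome_slices():
            assert np.all(np.diff(out.positions[idx]) >= 0)
        assert set(two_chrom_map.loci) <= set(out.loci)


# ---------------------------------------------------------------------------
# multipoint conditional probabilities
# ---------------------------------------------------------------------------

class TestConditionalGenotypeProbs:
    def test_typed_locus_is_point_mass(self, small_map):
        calls = np.full((1, 10), MISSING)
        calls[0, 3] = 0
        probs = conditional_genotype_probs(calls, small_map, F2)
        np.testing.assert_allclose(probs[0, 3], [1.0, 0.0, 0.0], atol=1e-12)

    def test_dh_midpoint_two_point_closed_form(self):
        # pseudomarker midway between two markers typed the same state,
        # each 1 cM away: P(state 1) = (1-r)^2 / ((1-r)^2 + r^2)
        gmap = GeneticMap(["a", "p", "b"], ["1"] * 3, [0.0, 1.0, 2.0],
                          [False, True, False])
        calls = np.array([[0, MISSING, 0]])
        probs = conditional_genotype_probs(calls, gmap, DH)
        r = recomb_fraction(1.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert probs[0, 1, 0] == pytest.approx(expected, abs=1e-12)
        # cross-check against the exhaustive-path oracle
        want = exhaustive_posterior(calls[0], gmap, DH)
        np.testing.assert_allclose(probs[0], want, atol=1e-10)

    @pytest.mark.parametrize("cross", ALL_DESIGNS)
    def test_matches_exhaustive_path_enumeration(self, cross, rng):
        """Forward-backward equals brute-force path summation to 1e-10."""
        for trial in range(20):
            L = int(rng.integers(2, 6))
            pos = np.sort(rng.uniform(0, 40, size=L))
            gmap = GeneticMap([f"m{i}" for i in range(L)], ["1"] * L, pos)
            calls = rng.integers(0, cross.n_states, size=(1, L))
            missing = rng.random(L) < 0.5
            calls[0, missing] = MISSING
            got = conditional_genotype_probs(calls, gmap, cross)
            want = exhaustive_posterior(calls[0], gmap, cross)
            np.testing.assert_allclose(got[0], want, atol=1e-10)

    @pytest.mark.parametrize("cross", ALL_DESIGNS)
    def test_no_data_gives_mendelian_frequencies(self, cross, small_map):
        calls = np.full((2, 10), MISSING)
        probs = conditional_genotype_probs(calls, small_map, cross)
        expected = np.asarray(cross.frequencies)
        np.testing.assert_allclose(probs, np.broadcast_to(expected, probs.shape), atol=1e-12)

    def test_rows_normalized(self, rng):
        gmap = GeneticMap([f"m{i}" for i in range(8)], ["1"] * 4 + ["2"] * 4,
                          [0.0, 7.5, 20.0, 33.0, 0.0, 5.0, 12.0, 30.0])
        calls = rng.integers(0, 3, size=(5, 8))
        calls[rng.random((5, 8)) < 0.4] = MISSING
        probs = conditional_genotype_probs(calls, gmap, F2)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-9)

    def test_conflicting_calls_at_colocated_markers_rejected(self, two_chrom_map):
        # chromosome 2 has two markers at the same position; discordant typed
        # states there have zero likelihood
        calls = np.full((1, 8), MISSING)
        calls[0, 5], calls[0, 6] = 0, 2
        with pytest.raises(ValueError, match="zero likelihood"):
            conditional_genotype_probs(calls, two_chrom_map, F2)

    def test_out_of_range_call_rejected(self, small_map):
        calls = np.full((1, 10), MISSING)
        calls[0, 0] = 5
        with pytest.raises(ValueError):
            conditional_genotype_probs(calls, small_map, DH)


class TestCodeGenotypes:
    def test_f2_definitional_cases(self):
        probs = np.array([[[1.0, 0, 0], [0, 1.0, 0], [0.7, 0.2, 0.1]]])
        np.testing.assert_allclose(
            code_genotypes(probs, F2)[0], [1.0, 0.0, 0.6], atol=1e-12
        )

    @pytest.mark.parametrize("cross", ALL_DESIGNS)
    def test_codes_within_declared_range(self, cross, rng):
        p = rng.dirichlet(np.ones(cross.n_states), size=(6, 4))
        x = code_genotypes(p, cross)
        if cross.kind == "f2":
            assert np.all((-1 <= x) & (x <= 1))
        else:
            assert np.all((0 <= x) & (x <= 1))

    def test_state_indices_map_to_codes(self):
        states = np.array([[0, 1, 2]])
        np.testing.assert_allclose(code_genotypes(states, F2)[0], [1.0, 0.0, -1.0])
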
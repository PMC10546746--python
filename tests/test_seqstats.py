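"""Frequency, probability, information and stacking mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqlayers import (DNA, FrequencyMatrix, HeightMatrix, SequenceSet,
                       build_pfm, extract, simulate_sequences, stack, to_bits,
                       to_probability)
from seqlayers.seqstats import AlignmentError, AlphabetError

from conftest import random_counts_matrix


def brute_force_entropy_bits(counts):
    """Independent per-column IC oracle: direct summation of -p log2 p."""
    counts = np.asarray(counts, dtype=float)
    s = counts.shape[0]
    out = []
    for j in range(counts.shape[1]):
        total = counts[:, j].sum()
        if total == 0:
            out.append(0.0)
            continue
        p = counts[:, j] / total
        H = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        out.append(math.log2(s) - H)
    return np.array(out)


class TestBuildPfm:
    def test_direct_tally(self):
        pfm = build_pfm(SequenceSet(["AC", "AG"], DNA))
        assert pfm.letters == DNA
        assert pfm.counts[:, 0].tolist() == [2, 0, 0, 0]
        assert pfm.counts[:, 1].tolist() == [0, 1, 1, 0]

    def test_gap_contributes_to_no_letter(self):
        pfm = build_pfm(SequenceSet(["A-"], DNA))
        assert pfm.counts[:, 1].tolist() == [0, 0, 0, 0]

    def test_matches_independent_tally_of_simulated_draws(self):
        seqs = simulate_sequences("ACGTAC", n=100, mutation_rate=0.3, seed=11)
        pfm = build_pfm(seqs)
        # independent tally: count characters column by column
        for j in range(6):
            column = [s[j] for s in seqs.sequences]
            for i, letter in enumerate(DNA):
                assert pfm.counts[i, j] == column.count(letter)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            SequenceSet(["AC", "ACG"], DNA)

    def test_foreign_character_named_with_position(self):
        with pytest.raises(AlphabetError, match="'X'.*position 2"):
            SequenceSet(["AX"], DNA)


class TestProbability:
    def test_exact_fractions(self, dna_pfm_3100):
        p = to_probability(dna_pfm_3100)
        assert p.mode == "probability"
        assert p.heights[:, 0].tolist() == [0.75, 0.25, 0.0, 0.0]

    def test_conserved_column(self):
        pfm = FrequencyMatrix(DNA, np.array([[2.0, 0], [0, 0], [0, 0], [0, 1]]).reshape(4, 2))
        p = to_probability(pfm)
        assert p.heights[0, 0] == 1.0

    def test_all_zero_column_stays_zero(self):
        pfm = FrequencyMatrix(DNA, np.array([[1, 0], [0, 0], [0, 0], [0, 0]], dtype=float))
        p = to_probability(pfm)
        assert p.heights[:, 1].sum() == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nonzero_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        m = random_counts_matrix(rng)
        p = to_probability(FrequencyMatrix(DNA, m)).heights
        sums = p.sum(axis=0)
        nz = m.sum(axis=0) > 0
        assert np.allclose(sums[nz], 1.0, atol=1e-9)
        assert np.all(sums[~nz] == 0.0)


class TestBits:
    def test_uniform_column_zero_information(self):
        pfm = FrequencyMatrix(DNA, np.full((4, 1), 5.0))
        assert np.allclose(to_bits(pfm).heights, 0.0)

    def test_conserved_column_two_bits(self):
        pfm = FrequencyMatrix(DNA, np.array([[0.0], [0.0], [8.0], [0.0]]))
        h = to_bits(pfm).heights
        assert h[2, 0] == pytest.approx(2.0)
        assert h.sum() == pytest.approx(2.0)

    def test_3100_column_against_entropy_oracle(self, dna_pfm_3100):
        h = to_bits(dna_pfm_3100).heights[:, 0]
        ic = brute_force_entropy_bits(dna_pfm_3100.counts)[0]
        assert ic == pytest.approx(1.188722, abs=1e-6)
        assert h.sum() == pytest.approx(ic, abs=1e-9)
        assert h[0] == pytest.approx(0.75 * ic, abs=1e-9)
        assert h[1] == pytest.approx(0.25 * ic, abs=1e-9)

    def test_small_sample_correction_subtracts_en_and_clamps(self):
        pfm = FrequencyMatrix(DNA, np.array([[0.0], [0.0], [8.0], [0.0]]))
        h = to_bits(pfm, small_sample_correction=True).heights
        e_n = 3 / (2 * math.log(2) * 8)
        assert h[2, 0] == pytest.approx(2.0 - e_n)
        # a uniform column's corrected IC clamps at zero instead of going negative
        uni = FrequencyMatrix(DNA, np.full((4, 1), 1.0))
        assert np.all(to_bits(uni, small_sample_correction=True).heights == 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_column_sums_bounded_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_counts_matrix(rng)
        h = to_bits(FrequencyMatrix(DNA, m)).heights
        sums = h.sum(axis=0)
        assert np.all(sums >= -1e-9)
        assert np.all(sums <= 2.0 + 1e-9)
        assert np.allclose(sums, brute_force_entropy_bits(m), atol=1e-9)


def brute_force_stack(letters, column):
    """Oracle: sort-then-cumulate, independent of the implementation."""
    pos = sorted(((v, i) for i, v in enumerate(column) if v > 0))
    neg = sorted(((-v, i) for i, v in enumerate(column) if v < 0))
    intervals = {}
    y = 0.0
    for v, i in pos:
        intervals[letters[i]] = (y, y + v)
        y += v
    y = 0.0
    for mag, i in neg:
        intervals[letters[i]] = (y - mag, y)
        y -= mag
    return intervals


class TestStack:
    def test_tallest_on_top(self):
        hm = HeightMatrix(DNA, np.array([[0.5], [0.3], [0.2], [0.0]]), "custom")
        ivs = {i.letter: (i.y_lo, i.y_hi) for i in stack(hm)}
        assert ivs == {"G": (0.0, pytest.approx(0.2)),
                       "C": (pytest.approx(0.2), pytest.approx(0.5)),
                       "A": (pytest.approx(0.5), pytest.approx(1.0))}

    def test_sign_split(self):
        hm = HeightMatrix(DNA, np.array([[1.0], [-0.5], [0.0], [0.0]]), "custom")
        ivs = {i.letter: (i.y_lo, i.y_hi) for i in stack(hm)}
        assert ivs["A"] == (0.0, 1.0)
        assert ivs["C"] == (-0.5, 0.0)

    def test_ties_break_by_alphabet_order_earlier_lower(self):
        hm = HeightMatrix(DNA, np.array([[0.5], [0.5], [0.0], [0.0]]), "custom")
        ivs = {i.letter: (i.y_lo, i.y_hi) for i in stack(hm)}
        assert ivs["A"] == (0.0, 0.5)
        assert ivs["C"] == (0.5, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3, allow_nan=False, width=32),
                    min_size=4, max_size=4))
    def test_matches_brute_force_oracle(self, column):
        hm = HeightMatrix(DNA, np.array(column).reshape(4, 1), "custom")
        got = {i.letter: (i.y_lo, i.y_hi) for i in stack(hm)}
        expected = brute_force_stack(DNA, column)
        assert set(got) == set(expected)
        for letter in got:
            assert got[letter] == pytest.approx(expected[letter], abs=1e-9)
        # partition of [0, sum positives]: no gaps, no overlaps, argmax on top
        pos = sorted((v for v in column if v > 0))
        if pos:
            top = max(got.values(), key=lambda iv: iv[1])
            assert top[1] == pytest.approx(sum(pos), abs=1e-9)


class TestExtract:
    def test_window(self):
        assert extract(["ABCDEF"], start=2, width=3) == ["BCD"]

    def test_identity_window(self):
        assert extract(["AB"], start=1, width=2) == ["AB"]

    def test_out_of_range_names_sequence(self):
        with pytest.raises(IndexError, match="sequence 2"):
            extract(["ABCD", "AB"], start=2, width=3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_lengths_equal_width(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        L = int(rng.integers(3, 20))
        seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
        start = int(rng.integers(1, L))
        width = int(rng.integers(1, L - start + 2))
        out = extract(seqs, start, width)
        assert all(len(s) == width for s in out)
        assert extract(seqs, 1, L) == seqs


class TestSimulate:
    def test_zero_rate_reproduces_consensus(self):
        seqs = simulate_sequences("ACGT", n=10, mutation_rate=0.0, seed=1)
        assert all(s == "ACGT" for s in seqs.sequences)

    def test_full_rate_binary_alphabet_flips_everything(self):
        seqs = simulate_sequences("AAAA", n=20, mutation_rate=1.0,
                                  alphabet="AC", seed=2)
        assert all(s == "CCCC" for s in seqs.sequences)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_sequences("ACGTAC", 25, 0.4, seed=33)
        b = simulate_sequences("ACGTAC", 25, 0.4, seed=33)
        assert a.sequences == b.sequences

    def test_consensus_frequency_within_three_standard_errors(self):
        n, rate = 2000, 0.2
        seqs = simulate_sequences("ACGTACGT", n=n, mutation_rate=rate, seed=7)
        se = math.sqrt(rate * (1 - rate) / n)
        for j, c in enumerate("ACGTACGT"):
            freq = sum(s[j] == c for s in seqs.sequences) / n
            assert abs(freq - (1 - rate)) <= 3 * se

    def test_consensus_argmax_property(self):
        seqs = simulate_sequences("TGCA", n=9, mutation_rate=0.0, seed=5)
        pfm = build_pfm(seqs)
        for j, c in enumerate("TGCA"):
            i = int(np.argmax(pfm.counts[:, j]))
            assert pfm.letters[i] == c
            assert pfm.counts[i, j] == 9
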
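"""Symbolic entropy core: symbolization, words, SE/CSE/NCSE, MNCSE profile."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mncse import (
    SymbolSequence,
    coarse_grain,
    corrected_shannon,
    cse_max,
    generate_pink,
    generate_wgn,
    mncse_profile,
    ncse,
    ncse_series,
    shannon_entropy,
    symbolize,
    words,
)

LN2 = math.log(2.0)


def brute_ncse(series, L=3, xi=2):
    """Literal reimplementation of the mean-threshold word-entropy chain.

    Independent of the package internals: pure-Python lists, a Counter
    histogram, and the closed-form bias correction evaluated digit by
    digit.
    """
    y = [float(v) for v in series]
    mean = sum(y) / len(y)
    s = [1 if v >= mean else 0 for v in y]
    word_list = [
        sum(s[j + k] * xi**k for k in range(L))
        for j in range(len(s) - L + 1)
    ]
    counts = Counter(word_list)
    n = len(word_list)
    se = -sum((c / n) * math.log2(c / n) for c in counts.values())
    M = xi**L
    cse = se + (len(counts) - 1) / (2 * M * LN2)
    cse_maximum = math.log2(M) + (M - 1) / (2 * M * LN2)
    return cse / cse_maximum


class TestSymbolize:
    def test_constant_series_all_ones(self):
        # equality with the mean maps to symbol 1
        np.testing.assert_array_equal(
            symbolize([5.0, 5.0, 5.0, 5.0]).symbols, [1, 1, 1, 1]
        )

    def test_alternating_series(self):
        np.testing.assert_array_equal(
            symbolize([1, 0, 1, 0, 1, 0]).symbols, [1, 0, 1, 0, 1, 0]
        )

    def test_symmetric_pair(self):
        np.testing.assert_array_equal(symbolize([-3.0, 3.0]).symbols, [0, 1])

    def test_threshold_uses_this_scale(self, rng):
        # the mean is recomputed on the coarse-grained series, so an
        # offset confined to the second half flips symbols only once
        # averaging has mixed it in
        x = rng.standard_normal(100)
        cg = coarse_grain(x, 4)
        sym = symbolize(cg)
        expected = (cg.values >= cg.values.mean()).astype(int)
        np.testing.assert_array_equal(sym.symbols, expected)
        assert sym.scale == 4

    def test_binary_symbol_count_matches_threshold(self, rng):
        y = rng.standard_normal(500)
        sym = symbolize(y)
        assert sym.symbols.sum() == (y >= y.mean()).sum()

    def test_unsupported_alphabet_rejected(self):
        with pytest.raises(ValueError, match="quantization"):
            symbolize([1.0, 2.0, 3.0], xi=3)

    def test_explicit_partition_enables_larger_alphabet(self):
        sym = symbolize([0.1, 0.5, 0.9], xi=3, partition=[0.3, 0.7])
        np.testing.assert_array_equal(sym.symbols, [0, 1, 2])


class TestWords:
    def test_eight_possible_words_for_binary_length_three(self, rng):
        h = words(symbolize(rng.standard_normal(200)), L=3)
        assert h.M == 8
        assert h.counts.size == 8  # word indices 0..7
        assert h.n_words == 198

    def test_hand_evaluated_example(self):
        h = words(SymbolSequence(np.array([1, 0, 1, 0, 1]), xi=2), L=3)
        assert h.counts[5] == 2 and h.counts[2] == 1
        assert h.n_words == 3 and h.C_R == 2

    def test_all_zero_symbols(self):
        h = words(SymbolSequence(np.zeros(4, dtype=int), xi=2), L=3)
        assert h.counts[0] == 2 and h.C_R == 1

    def test_too_few_symbols(self):
        with pytest.raises(ValueError, match="too few symbols"):
            words(SymbolSequence(np.array([1, 0]), xi=2), L=3)


class TestEntropyFormulas:
    def test_uniform_eight_words_gives_three_bits(self):
        from mncse import WordHistogram

        h = WordHistogram(np.full(8, 5), L=3, xi=2)
        assert shannon_entropy(h) == pytest.approx(3.0)

    def test_single_word_gives_zero(self):
        from mncse import WordHistogram

        h = WordHistogram([0, 0, 7, 0, 0, 0, 0, 0], L=3, xi=2)
        assert shannon_entropy(h) == 0.0
        assert corrected_shannon(h) == 0.0  # correction vanishes at C_R = 1
        assert ncse(h) == 0.0

    def test_two_word_example(self):
        from mncse import WordHistogram

        h = WordHistogram([0, 0, 1, 0, 0, 2, 0, 0], L=3, xi=2)
        assert shannon_entropy(h) == pytest.approx(0.9183, abs=5e-5)
        assert corrected_shannon(h) == pytest.approx(
            0.9182958 + 1 / (16 * LN2), abs=1e-6
        )
        assert ncse(h) == pytest.approx(0.2777, abs=5e-5)

    def test_cse_max_values(self):
        assert cse_max(3, 2) == pytest.approx(3.0 + 7 / (16 * LN2), abs=1e-12)
        assert cse_max(3, 2) == pytest.approx(3.6312, abs=5e-5)
        assert cse_max(1, 2) == pytest.approx(1.3607, abs=5e-5)

    def test_cse_max_increases_with_word_length(self):
        values = [cse_max(L, 2) for L in range(1, 8)]
        assert np.all(np.diff(values) > 0)

    def test_uniform_occupation_attains_exactly_one(self):
        from mncse import WordHistogram

        h = WordHistogram(np.full(8, 3), L=3, xi=2)
        assert ncse(h) == pytest.approx(1.0, abs=1e-15)


class TestNCSEEndpoints:
    def test_constant_series_is_zero(self):
        assert ncse_series(np.full(50, 2.7)) == 0.0

    def test_de_bruijn_cover_is_one(self):
        # 0001011100: its 8 overlapping 3-words cover all of 0..7 once
        series = [0, 0, 0, 1, 0, 1, 1, 1, 0, 0]
        assert ncse_series(series) == pytest.approx(1.0, abs=1e-15)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=4,
        max_size=60,
    ),
    L=st.integers(min_value=2, max_value=4),
)
def test_ncse_bounded_and_matches_bruteforce(data, L):
    """NCSE stays in [0, 1] and equals the literal chain to 1e-12."""
    if len(data) < L:
        return
    value = ncse(words(symbolize(np.asarray(data)), L=L))
    assert 0.0 <= value <= 1.0
    assert value == pytest.approx(brute_ncse(data, L=L), abs=1e-12)


def test_pipeline_matches_bruteforce_on_random_series(rng):
    for _ in range(100):
        n = int(rng.integers(5, 51))
        x = rng.standard_normal(n)
        assert ncse_series(x) == pytest.approx(brute_ncse(x), abs=1e-12)


class TestMNCSEProfile:
    def test_scale_one_reduces_to_single_scale_ncse(self, rng):
        x = rng.standard_normal(300)
        prof = mncse_profile(x, tau_max=1)
        assert prof.values[0] == pytest.approx(ncse_series(x), abs=1e-15)

    def test_all_scales_defined_when_long_enough(self):
        x = generate_wgn(100, seed=4)
        prof = mncse_profile(x, tau_max=20)
        needed = np.array([100 // tau >= 3 for tau in prof.scales])
        assert prof.defined[needed].all()
        assert np.all((prof.values[prof.defined] >= 0)
                      & (prof.values[prof.defined] <= 1))

    def test_too_short_scale_marked_undefined_with_warning(self):
        x = generate_wgn(10, seed=4)
        with pytest.warns(UserWarning, match="undefined"):
            prof = mncse_profile(x, tau_max=5)
        assert prof.defined[:3].all()  # floor(10/tau) >= 3 for tau <= 3
        assert not prof.defined[4]  # floor(10/5) = 2 < L
        assert prof.n_undefined >= 1

    def test_metadata_carried(self):
        prof = mncse_profile(generate_wgn(100, seed=1, label="g"), 5)
        assert prof.method == "MNCSE"
        assert prof.source_id == "wgn-1" and prof.label == "g"
        assert prof.params["L"] == 3 and prof.params["xi"] == 2


def test_shuffling_pink_noise_closes_gap_to_wgn():
    """Word statistics see temporal order: destroying the 1/f
    correlations by shuffling moves its NCSE to the white-noise level."""
    rng = np.random.default_rng(0)
    gaps_orig, gaps_shuf = [], []
    for seed in range(10):
        w = ncse_series(generate_wgn(2000, seed))
        p = generate_pink(2000, 100 + seed).values
        gaps_orig.append(abs(ncse_series(p) - w))
        gaps_shuf.append(abs(ncse_series(rng.permutation(p)) - w))
    assert np.mean(gaps_shuf) <= np.mean(gaps_orig)


def test_profile_frame_round_trip(rng):
    from mncse import frame_to_profiles, mse_profile, profiles_to_frame

    profs = [
        mncse_profile(generate_wgn(200, s, label="a"), 6) for s in (1, 2)
    ] + [mse_profile(generate_wgn(200, 3, label="b"), 6)]
    df = profiles_to_frame(profs)
    back = frame_to_profiles(df)
    assert len(back) == 3
    for orig, rebuilt in zip(profs, back):
        assert rebuilt.method == orig.method
        assert rebuilt.source_id == orig.source_id
        np.testing.assert_allclose(rebuilt.values, orig.values)
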
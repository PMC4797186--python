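import itertools

import numpy as np
import pytest

from _enumeration import EnumerationOracle
from entroprof.kmers import code_word
from entroprof.moments import (
    batch_entropy_moments,
    count_covariance,
    count_variance,
    entropy_variance,
    expected_count,
    expected_entropy,
    overlap_indicator,
    overlap_indicator_left,
    overlap_indicator_right,
    word_moments,
)
from entroprof.weights import WeightScheme, gaussian_weights

ALL_WORDS = [
    "".join(p) for k in (1, 2, 3) for p in itertools.product("ACGT", repeat=k)
]


class TestExpectations:
    def test_expected_count_uniform(self, uniform_m0):
        assert expected_count(uniform_m0, "AA", 10) == pytest.approx(9 / 16)

    def test_single_window(self, stationary_m1):
        from entroprof.background import word_probability

        assert expected_count(stationary_m1, "ACG", 3) == pytest.approx(
            word_probability(stationary_m1, "ACG")
        )

    def test_word_longer_than_sequence(self, uniform_m0):
        assert expected_count(uniform_m0, "ACGT", 3) == 0.0

    def test_expected_entropy_two_terms(self, uniform_m0):
        w = WeightScheme(2, np.array([1.0, 1.0]))
        assert expected_entropy(uniform_m0, "AA", w, 10) == pytest.approx(
            (10 * 0.25 + 9 * 0.0625) / 2
        )

    def test_degenerate_kernel_reduces_to_count(self, skewed_m0):
        w = WeightScheme(2, np.array([0.0, 1.0]))
        assert expected_entropy(skewed_m0, "CA", w, 25) == pytest.approx(
            expected_count(skewed_m0, "CA", 25)
        )


class TestOverlapIndicators:
    @pytest.mark.parametrize(
        "w,u,expected",
        [("ATA", 1, 1), ("AATA", 2, 0), ("AAAA", 3, 1), ("ACGT", 0, 1)],
    )
    def test_self_overlap(self, w, u, expected):
        assert overlap_indicator(w, u) == expected

    @pytest.mark.parametrize(
        "w_short,w_long,u,expected",
        [("CA", "AGC", 1, 1), ("CA", "GGC", 1, 0), ("CA", "AGC", 0, 1)],
    )
    def test_left(self, w_short, w_long, u, expected):
        assert overlap_indicator_left(w_short, w_long, u) == expected

    @pytest.mark.parametrize(
        "w_long,w_short,u,expected",
        [
            ("AGCC", "CC", 2, 1),  # w'' occupies the last two positions
            ("AGCC", "GC", 3, 1),  # aligned placement at offset k'-u+1
            ("AGCC", "AG", 1, 0),  # suffix C != prefix A
            ("AGCC", "AG", 4, 1),  # prefix placement at offset 1
        ],
    )
    def test_right(self, w_long, w_short, u, expected):
        assert overlap_indicator_right(w_long, w_short, u) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            overlap_indicator("ACG", 4)


class TestCountMomentsAgainstEnumeration:
    """Closed-form count moments vs probability-weighted exhaustion of 4**l
    sequences (small l here; the full sweep runs in the acceptance suite)."""

    def test_variance_anchor(self, uniform_m0):
        assert count_variance(uniform_m0, "AA", 3) == pytest.approx(9 / 64)

    def test_covariance_anchor(self, uniform_m0):
        assert count_covariance(uniform_m0, "AA", "A", 2) == pytest.approx(3 / 32)

    def test_whole_word_is_bernoulli(self, stationary_m1):
        from entroprof.background import word_probability

        mu = word_probability(stationary_m1, "GAT")
        assert count_variance(stationary_m1, "GAT", 3) == pytest.approx(
            mu * (1 - mu)
        )

    @pytest.mark.parametrize("l", [3, 4])
    def test_small_enumeration_sweep(self, stationary_m1, l):
        oracle = EnumerationOracle(stationary_m1, l, ALL_WORDS)
        for w in ALL_WORDS:
            assert count_variance(stationary_m1, w, l) == pytest.approx(
                oracle.variance(w), abs=1e-12
            )
            for k2 in range(1, len(w)):
                assert count_covariance(
                    stationary_m1, w, w[-k2:], l
                ) == pytest.approx(oracle.covariance(w, w[-k2:]), abs=1e-12)

    def test_covariance_symmetric_in_arguments(self, stationary_m1):
        a = count_covariance(stationary_m1, "ACA", "CA", 12)
        b = count_covariance(stationary_m1, "CA", "ACA", 12)
        assert a == b

    def test_non_suffix_pair_rejected(self, uniform_m0):
        with pytest.raises(ValueError):
            count_covariance(uniform_m0, "ACGT", "AC", 10)

    def test_variance_nonnegative_with_all_terms(self, stationary_m1):
        for w in ("AAAA", "ATAT", "ACGT", "TTTA"):
            assert count_variance(stationary_m1, w, 30) >= 0.0


class TestEntropyVariance:
    def test_degenerate_kernel_is_count_variance(self, stationary_m1):
        w = WeightScheme(3, np.array([0.0, 0.0, 1.0]))
        assert entropy_variance(stationary_m1, "GCA", w, 20) == pytest.approx(
            count_variance(stationary_m1, "GCA", 20)
        )

    @pytest.mark.parametrize("word", ["AATA", "GCGC"])
    def test_matches_enumeration(self, stationary_m1, word):
        suffixes = [word[-k:] for k in range(1, len(word) + 1)]
        oracle = EnumerationOracle(stationary_m1, 6, suffixes)
        w = gaussian_weights(4, 1.2)
        _, var_ref = oracle.entropy_moments(word, w)
        assert entropy_variance(stationary_m1, word, w, 6) == pytest.approx(
            var_ref, abs=1e-10
        )

    def test_monte_carlo_consistency(self, uniform_m0, rng):
        """Empirical Var[SE_w] over simulated chains within 3 SE of exact."""
        l, n = 30, 20000
        X = rng.integers(0, 4, size=(n, l))
        w = gaussian_weights(3, 1.0)
        for word in ("AAA", "ACG"):
            counts = np.zeros((3, n))
            for k in range(1, 4):
                s = word[-k:]
                match = np.ones((n, l - k + 1), dtype=bool)
                for j, a in enumerate(s):
                    match &= X[:, j : l - k + 1 + j] == "ACGT".index(a)
                counts[k - 1] = match.sum(axis=1)
            se = w.values @ counts / w.total
            emp = se.var(ddof=1)
            dev = se - se.mean()
            se_of_var = np.sqrt((np.mean(dev**4) - emp**2) / n)
            exact = entropy_variance(uniform_m0, word, w, l)
            assert abs(emp - exact) < 3 * se_of_var

    def test_neglected_terms_are_small_and_stabilise(self, stationary_m1):
        """Dropping the disjoint terms is a small, controlled approximation.

        Under an order-0 model the disjoint terms are identically zero.
        Under a first-order chain both the disjoint sum and the variance
        grow linearly with l, so the relative gap converges to a small
        constant rather than vanishing: successive differences of the gap
        shrink and the limit stays at the percent level.
        """
        w = gaussian_weights(4, 1.0)
        base = np.full(4, 0.25)
        m0 = type(stationary_m1)(0, base, np.tile(base, (4, 1)), 0.0)
        assert entropy_variance(m0, "ATAT", w, 100, True) == pytest.approx(
            entropy_variance(m0, "ATAT", w, 100, False), abs=1e-12
        )
        gaps = []
        for l in (50, 200, 1000):
            full = entropy_variance(stationary_m1, "ATAT", w, l, True)
            trunc = entropy_variance(stationary_m1, "ATAT", w, l, False)
            gaps.append(abs(full - trunc) / full)
        assert abs(gaps[2] - gaps[1]) < abs(gaps[1] - gaps[0])
        assert gaps[2] < 0.05

    def test_word_moments_assembly(self, stationary_m1):
        w = gaussian_weights(3, 0.8)
        wm = word_moments(stationary_m1, "TGA", w, 15)
        assert np.allclose(wm.covariance, wm.covariance.T)
        assert np.all(np.diag(wm.covariance) >= 0)
        recomputed = w.values @ wm.covariance @ w.values / w.total**2
        assert wm.variance == pytest.approx(recomputed, abs=1e-10)


class TestBatchMoments:
    @pytest.mark.parametrize("include_nonoverlap", [False, True])
    @pytest.mark.parametrize("model_name", ["uniform_m0", "stationary_m1"])
    def test_batch_equals_scalar(
        self, request, model_name, include_nonoverlap, rng
    ):
        model = request.getfixturevalue(model_name)
        w = gaussian_weights(3, 1.1)
        E, V = batch_entropy_moments(model, w, 21, include_nonoverlap)
        for code in rng.choice(64, size=16, replace=False):
            word = code_word(int(code), 3)
            assert E[code] == pytest.approx(
                expected_entropy(model, word, w, 21), abs=1e-12
            )
            assert V[code] == pytest.approx(
                entropy_variance(model, word, w, 21, include_nonoverlap),
                abs=1e-10,
            )
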
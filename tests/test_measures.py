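import itertools

import numpy as np
import pytest

from conftest import random_dna
from entroprof.measures import (
    all_word_probabilities,
    d2,
    d2s,
    d2star,
    ep2,
    ep2star,
    pairwise_matrix,
)
from entroprof.background import estimate_model, word_probability
from entroprof.kmers import count_occurrences
from entroprof.sequence import Sequence


def brute_force_d2(seqA, seqB, k):
    total = 0
    for p in itertools.product("ACGT", repeat=k):
        w = "".join(p)
        total += count_occurrences(seqA, w) * count_occurrences(seqB, w)
    return total


def brute_force_d2s(seqA, seqB, k, order=1):
    mA = estimate_model(seqA, order)
    mB = estimate_model(seqB, order)
    total = 0.0
    for p in itertools.product("ACGT", repeat=k):
        w = "".join(p)
        ca = count_occurrences(seqA, w) - (seqA.l - k + 1) * word_probability(mA, w)
        cb = count_occurrences(seqB, w) - (seqB.l - k + 1) * word_probability(mB, w)
        den = np.sqrt(ca**2 + cb**2)
        if den > 0:
            total += ca * cb / den
    return total


class TestFixedResolution:
    def test_d2_self_comparison(self):
        s = Sequence("a", "AAAA")
        assert d2(s, s, 2) == 9  # c_AA^2

    def test_d2_disjoint_content(self):
        assert d2(Sequence("a", "AAAA"), Sequence("b", "CCCC"), 2) == 0

    def test_d2_matches_brute_force(self, rng):
        A, B = random_dna(rng, 120, "a"), random_dna(rng, 90, "b")
        assert d2(A, B, 3) == brute_force_d2(A, B, 3)

    def test_d2s_matches_brute_force(self, rng):
        A, B = random_dna(rng, 150, "a"), random_dna(rng, 150, "b")
        assert d2s(A, B, 2) == pytest.approx(brute_force_d2s(A, B, 2))

    def test_d2star_matches_brute_force(self, rng):
        A, B = random_dna(rng, 150, "a"), random_dna(rng, 110, "b")
        k = 2
        mA, mB = estimate_model(A, 1), estimate_model(B, 1)
        n = np.sqrt(A.l * B.l)
        total = 0.0
        for p in itertools.product("ACGT", repeat=k):
            w = "".join(p)
            pa, pb = word_probability(mA, w), word_probability(mB, w)
            ca = count_occurrences(A, w) - (A.l - k + 1) * pa
            cb = count_occurrences(B, w) - (B.l - k + 1) * pb
            total += ca * cb / ((n - k + 1) * np.sqrt(pa * pb))
        assert d2star(A, B, k) == pytest.approx(total)

    def test_word_probabilities_sum_to_one(self, stationary_m1):
        for k in (1, 2, 4):
            assert all_word_probabilities(stationary_m1, k).sum() == pytest.approx(
                1.0
            )

    def test_k_out_of_range(self, rng):
        A, B = random_dna(rng, 10, "a"), random_dna(rng, 10, "b")
        with pytest.raises(ValueError):
            d2(A, B, 11)


class TestSymmetry:
    @pytest.mark.parametrize("measure", ["d2", "d2s", "d2star", "ep2", "ep2star"])
    def test_swap_invariance(self, measure, rng):
        A, B = random_dna(rng, 180, "a"), random_dna(rng, 140, "b")
        kwargs = {"k": 3} if measure.startswith("d2") else {"L": 3, "sigma": 0.7}
        fn = {"d2": d2, "d2s": d2s, "d2star": d2star, "ep2": ep2, "ep2star": ep2star}[
            measure
        ]
        if measure == "d2":
            ab, ba = fn(A, B, 3), fn(B, A, 3)
        elif measure.startswith("d2"):
            ab, ba = fn(A, B, 3), fn(B, A, 3)
        else:
            ab, ba = fn(A, B, 3, 0.7), fn(B, A, 3, 0.7)
        assert ab == pytest.approx(ba, abs=1e-10)


class TestSigmaDegeneration:
    def test_ep2_converges_to_d2(self, rng):
        A, B = random_dna(rng, 500, "a"), random_dna(rng, 500, "b")
        assert ep2(A, B, 4, sigma=0.01) == pytest.approx(d2(A, B, 4), abs=1e-9)

    def test_ep2star_poisson_converges_to_d2star(self, rng):
        A, B = random_dna(rng, 500, "a"), random_dna(rng, 500, "b")
        assert ep2star(A, B, 4, sigma=0.01, variance="poisson") == pytest.approx(
            d2star(A, B, 4), abs=1e-6
        )


class TestEp2Star:
    def test_self_similarity_ranks_top(self, rng):
        """A sequence scores itself above random sequences of the same
        composition (rank property of the centred statistic)."""
        A = random_dna(rng, 400, "a")
        self_score = ep2star(A, A, 3, sigma=0.7)
        others = [
            ep2star(A, random_dna(rng, 400, f"b{i}"), 3, sigma=0.7)
            for i in range(30)
        ]
        assert self_score > max(others)

    def test_revcomp_mode_finite_and_symmetric(self, rng):
        A, B = random_dna(rng, 300, "a"), random_dna(rng, 300, "b")
        ab = ep2star(A, B, 3, sigma=0.7, revcomp=True)
        ba = ep2star(B, A, 3, sigma=0.7, revcomp=True)
        assert np.isfinite(ab)
        assert ab == pytest.approx(ba, abs=1e-10)

    def test_detects_reverse_complement_content(self, rng):
        """With strand classes on, the reverse complement of a sequence
        ranks above unrelated sequences of the same composition."""
        from entroprof.kmers import reverse_complement

        A = random_dna(rng, 400, "a")
        Arc = Sequence("arc", reverse_complement(A.residues))
        rc_score = ep2star(A, Arc, 3, sigma=0.7, revcomp=True)
        others = [
            ep2star(A, random_dna(rng, 400, f"b{i}"), 3, sigma=0.7, revcomp=True)
            for i in range(30)
        ]
        assert rc_score > max(others)

    def test_invalid_variance_convention(self, rng):
        A, B = random_dna(rng, 50, "a"), random_dna(rng, 50, "b")
        with pytest.raises(ValueError):
            ep2star(A, B, 2, sigma=0.7, variance="bogus")


class TestPairwiseMatrix:
    def test_two_sequences_single_value(self, rng):
        seqs = [random_dna(rng, 100, "a"), random_dna(rng, 100, "b")]
        result = pairwise_matrix(seqs, "d2", k=2)
        assert result.matrix[0, 1] == result.matrix[1, 0]
        assert result.pair_scores().shape == (1,)
        assert result.matrix[0, 1] == d2(seqs[0], seqs[1], 2)

    def test_pair_count(self, rng):
        seqs = [random_dna(rng, 80, f"s{i}") for i in range(8)]
        result = pairwise_matrix(seqs, "ep2", L=2, sigma=0.5)
        assert result.pair_scores().shape == (28,)

    def test_order_invariance(self, rng):
        seqs = [random_dna(rng, 90, f"s{i}") for i in range(5)]
        fwd = pairwise_matrix(seqs, "d2star", k=2).to_frame()
        perm = [3, 1, 4, 0, 2]
        rev = pairwise_matrix([seqs[i] for i in perm], "d2star", k=2).to_frame()
        ids = fwd.index.tolist()
        assert np.allclose(rev.loc[ids, ids].values, fwd.values)

    def test_matches_single_pair_functions(self, rng):
        seqs = [random_dna(rng, 150, f"s{i}") for i in range(4)]
        result = pairwise_matrix(
            seqs, "ep2star", L=3, sigma=0.7, revcomp=True
        )
        direct = ep2star(seqs[0], seqs[2], 3, sigma=0.7, revcomp=True)
        assert result.matrix[0, 2] == pytest.approx(direct, abs=1e-10)

    def test_unknown_measure(self, rng):
        seqs = [random_dna(rng, 50, "a"), random_dna(rng, 50, "b")]
        with pytest.raises(ValueError, match="unknown measure"):
            pairwise_matrix(seqs, "n2", k=2)

    def test_long_format(self, rng):
        seqs = [random_dna(rng, 60, f"s{i}") for i in range(3)]
        frame = pairwise_matrix(seqs, "d2", k=2).to_long()
        assert len(frame) == 3
        assert set(frame.columns) == {"idA", "idB", "measure", "resolution", "score"}
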
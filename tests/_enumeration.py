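"""Brute-force enumeration oracle for word-count moments.

Enumerates every sequence of length l over {A,C,G,T}, weights each by its
probability under a background model, and computes exact moments of word
counts by direct summation.  Deliberately independent of the package's
closed-form moment code: counts come from naive window comparison and
moments from probability-weighted sums over all 4**l sequences.
"""

from __future__ import annotations

import itertools
from typing import Sequence as TypingSequence

import numpy as np

from entroprof.sequence import LETTER_CODE


class EnumerationOracle:
    def __init__(self, model, l: int, words: TypingSequence[str]):
        seqs = np.array(
            list(itertools.product(range(4), repeat=l)), dtype=np.int64
        )
        probs = model.base_probs[seqs[:, 0]].copy()
        for j in range(1, l):
            probs = probs * model.transitions[seqs[:, j - 1], seqs[:, j]]
        self.l = l
        self.probs = probs
        self.counts = {}
        for w in words:
            k = len(w)
            if k > l:
                self.counts[w] = np.zeros(len(seqs), dtype=np.int64)
                continue
            match = np.ones((len(seqs), l - k + 1), dtype=bool)
            for j, a in enumerate(w):
                match &= seqs[:, j : l - k + 1 + j] == LETTER_CODE[a]
            self.counts[w] = match.sum(axis=1)

    def expectation(self, w: str) -> float:
        return float(self.probs @ self.counts[w])

    def covariance(self, u: str, v: str) -> float:
        joint = float(self.probs @ (self.counts[u] * self.counts[v]))
        return joint - self.expectation(u) * self.expectation(v)

    def variance(self, w: str) -> float:
        return self.covariance(w, w)

    def entropy_moments(self, w: str, weights) -> tuple[float, float]:
        """Exact (E[SE_w], Var[SE_w]) by direct summation."""
        se = np.zeros(len(self.probs))
        for k in range(1, len(w) + 1):
            se = se + weights.values[k - 1] * self.counts[w[-k:]]
        se = se / weights.total
        mean = float(self.probs @ se)
        return mean, float(self.probs @ se**2) - mean**2
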
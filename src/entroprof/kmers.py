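"""Multi-resolution word counting.

A :class:`MultiResolutionCounts` index stores, for one sequence, the
occurrence counts of every word of length 1..L.  Occurrences may overlap;
windows containing an N are dropped from all counts.  Words are encoded as
base-4 integers with the first letter most significant, so the length-k
suffix of a word is simply its code modulo 4**k — the property the simple
entropy of a word is built on.

Counting is hash/bincount based over the observed windows; with the
enforced limit L <= 12 this is as fast as any specialised index at the
scales this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from entroprof.sequence import ALPHABET, LETTER_CODE, Sequence

#: hard cap on word length for dense count tables (4**12 = 16.7M entries)
MAX_L = 12

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(w: str) -> str:
    """Watson-Crick reverse complement of an unambiguous word."""
    w = w.upper()
    if set(w) - set(ALPHABET):
        raise ValueError(f"word {w!r} contains non-ACGT symbols")
    return w.translate(_COMPLEMENT)[::-1]


def word_code(w: str) -> int:
    """Base-4 integer code of a word (A=0, C=1, G=2, T=3, big-endian)."""
    code = 0
    for a in w.upper():
        code = code * 4 + LETTER_CODE[a]
    return code


def code_word(code: int, k: int) -> str:
    """Inverse of :func:`word_code` for words of length k."""
    letters = []
    for _ in range(k):
        letters.append(ALPHABET[code % 4])
        code //= 4
    return "".join(reversed(letters))


def count_occurrences(seq: Sequence, w: str) -> int:
    """Number of (possibly overlapping) occurrences of ``w`` in ``seq``.

    A window containing an N never matches.  A word longer than the
    sequence simply has zero occurrences.
    """
    w = w.upper()
    if not w:
        raise ValueError("word must be non-empty")
    if set(w) - set(ALPHABET):
        return 0
    if len(w) > seq.l:
        return 0
    count = 0
    start = seq.residues.find(w)
    while start != -1:
        count += 1
        start = seq.residues.find(w, start + 1)
    return count


@dataclass
class MultiResolutionCounts:
    """Dense occurrence-count tables for all words of length 1..L."""

    L: int
    l: int
    #: tables[k-1] is an int64 array of length 4**k of counts of length-k words
    tables: List[np.ndarray]

    def count(self, w: str) -> int:
        """Occurrence count of a word of length <= L (0 if absent)."""
        k = len(w)
        if k < 1 or k > self.L:
            raise ValueError(f"word length {k} outside index range 1..{self.L}")
        return int(self.tables[k - 1][word_code(w)])

    def dense(self, k: int) -> np.ndarray:
        """Count vector over all 4**k words of length k."""
        if k < 1 or k > self.L:
            raise ValueError(f"k={k} outside index range 1..{self.L}")
        return self.tables[k - 1]

    def suffix_counts(self, w: str) -> np.ndarray:
        """Counts (c_{w,1}, ..., c_{w,|w|}) of the suffixes of ``w``.

        Entry k (1-based) is the occurrence count of the length-k suffix.
        """
        k = len(w)
        if k > self.L:
            raise ValueError(f"|w|={k} exceeds index resolution L={self.L}")
        code = word_code(w)
        return np.array(
            [self.tables[j - 1][code % 4**j] for j in range(1, k + 1)],
            dtype=np.int64,
        )


def build_index(seq: Sequence, L: int) -> MultiResolutionCounts:
    """Count all words of length 1..L in one pass over the sequence."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if L > seq.l:
        raise ValueError(f"L={L} exceeds sequence length {seq.l}")
    if L > MAX_L:
        raise ValueError(f"L={L} exceeds the enforced limit {MAX_L}")
    x = seq.codes().astype(np.int64)
    valid = x >= 0
    tables: List[np.ndarray] = []
    codes = np.zeros(0, dtype=np.int64)
    ok = np.zeros(0, dtype=bool)
    for k in range(1, L + 1):
        if k == 1:
            codes = x.copy()
            ok = valid.copy()
        else:
            codes = codes[:-1] * 4 + x[k - 1 :]
            ok = ok[:-1] & valid[k - 1 :]
        tables.append(np.bincount(codes[ok], minlength=4**k).astype(np.int64))
    return MultiResolutionCounts(L=L, l=seq.l, tables=tables)


def suffix_counts(index: MultiResolutionCounts, w: str) -> np.ndarray:
    """Functional alias for :meth:`MultiResolutionCounts.suffix_counts`."""
    return index.suffix_counts(w)
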
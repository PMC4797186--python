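"""Simple entropies of words and per-position entropic profiles.

The *simple entropy* of a word w of length L in a sequence is the
kernel-weighted average of the occurrence counts of its suffixes,

    SE_w = sum_k a_k c_{w,k} / sum_k a_k,

where c_{w,k} counts the length-k suffix of w.  It is the multi-resolution
analogue of a k-mer count and the building block of the EP2/EP2* measures.

The per-position *entropic profile* is the single-sequence ancestor of
these statistics: for each position i it combines the counts of all
suffixes ending at i with geometric weights (4 phi)^k and standardises the
resulting curve by its own mean and standard deviation, highlighting
positions where over-represented words end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as TypingSequence, Tuple

import numpy as np

from entroprof.kmers import MultiResolutionCounts, build_index, word_code
from entroprof.sequence import Sequence
from entroprof.weights import WeightScheme


def simple_entropy(
    suffix_counts: TypingSequence[float] | np.ndarray, weights: WeightScheme
) -> float:
    """Weighted average of suffix counts: sum a_k c_k / sum a_k."""
    counts = np.asarray(suffix_counts, dtype=float)
    if counts.shape != (weights.L,):
        raise ValueError(
            f"expected {weights.L} suffix counts, got shape {counts.shape}"
        )
    return float(weights.values @ counts / weights.total)


def rc_codes(L: int) -> np.ndarray:
    """Reverse-complement code of every length-L word, vectorised."""
    codes = np.arange(4**L, dtype=np.int64)
    out = np.zeros_like(codes)
    rest = codes.copy()
    # peel letters from the least-significant (last) position; complement
    # (3 - letter) and re-emit most-significant first
    for _ in range(L):
        rest, letter = np.divmod(rest, 4)
        out = out * 4 + (3 - letter)
    return out


def canonical_classes(L: int) -> Tuple[np.ndarray, np.ndarray]:
    """Strand-equivalence classes {w, rc(w)} over all length-L words.

    Returns (reps, partners): the canonical representative (lexicographic
    minimum) of each class and its reverse complement.  Palindromic words
    form singleton classes (rep == partner).
    """
    codes = np.arange(4**L, dtype=np.int64)
    rc = rc_codes(L)
    mask = codes <= rc
    return codes[mask], rc[mask]


def all_simple_entropies(
    index: MultiResolutionCounts, weights: WeightScheme
) -> np.ndarray:
    """SE_w for every word w of length L, as an array indexed by word code."""
    L = weights.L
    if L > index.L:
        raise ValueError(f"weights L={L} exceeds index resolution {index.L}")
    codes = np.arange(4**L, dtype=np.int64)
    acc = np.zeros(4**L, dtype=float)
    for k in range(1, L + 1):
        acc += weights.values[k - 1] * index.dense(k)[codes % 4**k]
    return acc / weights.total


@dataclass
class EntropyVector:
    """Simple entropies of all length-L words of one sequence.

    ``values`` is indexed by word code over the full universe of 4**L
    words (absent words have entropy 0 only if all their suffixes are
    absent).  In reverse-complement mode the word universe collapses to
    strand classes {w, rc(w)} and each class takes the maximum entropy of
    its two members, attached to the lexicographically smaller word.
    """

    source: str
    l: int
    weights: WeightScheme
    revcomp: bool
    values: np.ndarray  # (4**L,) entropies by word code
    class_reps: Optional[np.ndarray] = None  # canonical codes (revcomp only)
    class_values: Optional[np.ndarray] = None  # per-class max entropy
    class_argmax: Optional[np.ndarray] = None  # code of the word attaining the max

    @property
    def L(self) -> int:
        return self.weights.L

    def value(self, w: str) -> float:
        """Entropy of a word, or of its strand class in revcomp mode."""
        if len(w) != self.L:
            raise ValueError(f"expected a word of length {self.L}, got {w!r}")
        code = word_code(w)
        if not self.revcomp:
            return float(self.values[code])
        rep = min(code, int(rc_codes(self.L)[code]))
        pos = int(np.searchsorted(self.class_reps, rep))
        return float(self.class_values[pos])


def entropy_vector(
    seq: Sequence,
    L: int,
    weights: WeightScheme,
    revcomp: bool = False,
    index: Optional[MultiResolutionCounts] = None,
) -> EntropyVector:
    """Compute SE_w for every length-L word (or strand class) of ``seq``."""
    if weights.L != L:
        raise ValueError(f"weights are for L={weights.L}, requested L={L}")
    if L > seq.l:
        raise ValueError(f"L={L} exceeds sequence length {seq.l}")
    if index is None:
        index = build_index(seq, L)
    values = all_simple_entropies(index, weights)
    if not revcomp:
        return EntropyVector(seq.id, seq.l, weights, False, values)
    reps, partners = canonical_classes(L)
    fwd, rev = values[reps], values[partners]
    take_fwd = fwd >= rev  # ties resolve to the canonical representative
    class_values = np.where(take_fwd, fwd, rev)
    class_argmax = np.where(take_fwd, reps, partners)
    return EntropyVector(
        seq.id, seq.l, weights, True, values, reps, class_values, class_argmax
    )


@dataclass
class PositionProfile:
    """Raw and standardised per-position entropic profile."""

    source: str
    L: int
    phi: float
    fhat: np.ndarray  # raw profile, one value per position
    ep: np.ndarray  # standardised profile (zeros when degenerate)
    mean: float
    std: float
    degenerate: bool


def position_profile(seq: Sequence, L: int, phi: float) -> PositionProfile:
    """Per-position entropic profile with its own-mean standardisation.

    The raw value at position i (1-based) is

        fhat(i) = (1 + (1/l) * sum_{k<=min(L,i)} (4 phi)^k c_k(i)) /
                  sum_{k=0..L} phi^k

    where c_k(i) counts the length-k word ending at i.  Positions i < L
    only receive the terms whose suffix fits.  The standardised profile
    subtracts the arithmetic mean and divides by the (n-1)-normalised
    standard deviation; a constant profile is flagged degenerate and its
    standardised values are defined as 0.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    L_eff = min(L, seq.l)
    index = build_index(seq, L_eff)
    x = seq.codes().astype(np.int64)
    valid = x >= 0
    l = seq.l
    numer = np.ones(l, dtype=float)
    codes = np.zeros(0, dtype=np.int64)
    ok = np.zeros(0, dtype=bool)
    for k in range(1, L_eff + 1):
        if k == 1:
            codes, ok = x.copy(), valid.copy()
        else:
            codes = codes[:-1] * 4 + x[k - 1 :]
            ok = ok[:-1] & valid[k - 1 :]
        counts = np.where(ok, index.dense(k)[np.where(ok, codes, 0)], 0)
        numer[k - 1 :] += (4.0 * phi) ** k * counts / l
    denom = sum(phi**k for k in range(0, L + 1))
    fhat = numer / denom
    m = float(fhat.mean())
    s = float(fhat.std(ddof=1)) if l > 1 else 0.0
    degenerate = s <= 0.0
    ep = np.zeros(l) if degenerate else (fhat - m) / s
    return PositionProfile(seq.id, L, phi, fhat, ep, m, s, degenerate)
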
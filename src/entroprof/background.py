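"""Stationary Markov background models of DNA composition.

An order-0 (Bernoulli, "M0") model is a single base distribution mu; an
order-1 ("M1") model adds a 4x4 row-stochastic transition matrix pi.  The
probability that a word w = w_1...w_k occurs at any fixed position of a
stationary chain is

    mu(w) = mu(w_1) * prod_{j=2}^{k} pi(w_{j-1}, w_j).

For order 0 the transition matrix is defined as pi(a, b) = mu(b) so that
both orders share one evaluation path.

Estimation uses add-``pseudocount`` smoothing (default 1.0) on letter and
dinucleotide counts so that every word probability is strictly positive;
standardised statistics divide by these probabilities.  N residues are
skipped for letter counts and break dinucleotide adjacency.  The initial
distribution of the chain is the (smoothed) empirical letter frequency, not
the stationary vector of pi; for estimated models the two differ only
slightly on long sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np

from entroprof.sequence import ALPHABET, LETTER_CODE, Sequence

_TOL = 1e-12


@dataclass
class BackgroundModel:
    """Order-0 or order-1 stationary Markov model over {A, C, G, T}."""

    order: int
    base_probs: np.ndarray  # shape (4,), sums to 1
    transitions: np.ndarray  # shape (4, 4), row-stochastic
    pseudocount: float = 1.0
    _powers: Dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError(f"model order must be 0 or 1, got {self.order}")
        self.base_probs = np.asarray(self.base_probs, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.base_probs.shape != (4,) or self.transitions.shape != (4, 4):
            raise ValueError("base_probs must have shape (4,), transitions (4, 4)")
        if abs(self.base_probs.sum() - 1.0) > _TOL:
            raise ValueError("base probabilities must sum to 1")
        if np.any(self.transitions < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > _TOL):
            raise ValueError("transition matrix rows must sum to 1")

    def mu(self, letter: str) -> float:
        """Base probability of a single letter."""
        return float(self.base_probs[LETTER_CODE[letter]])

    def power(self, t: int) -> np.ndarray:
        """t-th power of the transition matrix (memoised, repeated squaring)."""
        if t < 1:
            raise ValueError(f"t must be >= 1, got {t}")
        cached = self._powers.get(t)
        if cached is not None:
            return cached
        if t == 1:
            result = self.transitions
        elif t % 2 == 0:
            half = self.power(t // 2)
            result = half @ half
        else:
            result = self.power(t - 1) @ self.transitions
        self._powers[t] = result
        return result


def estimate_model(
    seq: Sequence, order: int = 1, pseudocount: float = 1.0
) -> BackgroundModel:
    """Estimate an M0 or M1 background model from a sequence.

    Letter counts are taken over non-N positions; dinucleotide counts over
    adjacent non-N pairs (an N breaks adjacency).  ``pseudocount`` is added
    to every letter and dinucleotide count before normalisation.
    """
    if order not in (0, 1):
        raise ValueError(f"model order must be 0 or 1, got {order}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = seq.codes()
    valid = codes >= 0
    n_valid = int(valid.sum())
    if n_valid < 1:
        raise ValueError(f"sequence {seq.id!r} has no unambiguous residues")
    letter_counts = np.bincount(codes[valid], minlength=4).astype(float)
    base = letter_counts + pseudocount
    if base.sum() == 0:
        raise ValueError("all letter counts and pseudocount are zero")
    base /= base.sum()

    if order == 0:
        trans = np.tile(base, (4, 1))
        return BackgroundModel(0, base, trans, pseudocount)

    first, second = codes[:-1], codes[1:]
    pair_ok = (first >= 0) & (second >= 0)
    if int(pair_ok.sum()) < 1 and pseudocount == 0:
        raise ValueError(
            f"sequence {seq.id!r} has no unbroken dinucleotides for order-1 estimation"
        )
    di = np.zeros((4, 4), dtype=float)
    np.add.at(di, (first[pair_ok], second[pair_ok]), 1.0)
    di += pseudocount
    row_sums = di.sum(axis=1, keepdims=True)
    # a letter never observed as a dinucleotide prefix carries no transition
    # information; give it the marginal letter distribution
    empty = row_sums[:, 0] == 0
    trans = np.empty((4, 4))
    trans[~empty] = di[~empty] / row_sums[~empty]
    trans[empty] = base
    return BackgroundModel(1, base, trans, pseudocount)


def word_probability(model: BackgroundModel, w: str) -> float:
    """Occurrence probability mu(w) of a word at a fixed position."""
    if not w:
        raise ValueError("word must be non-empty")
    try:
        idx = [LETTER_CODE[a] for a in w.upper()]
    except KeyError as exc:
        raise ValueError(f"word {w!r} contains non-ACGT symbols") from exc
    p = float(model.base_probs[idx[0]])
    for a, b in zip(idx, idx[1:]):
        p *= float(model.transitions[a, b])
    return p


def transition_power(model: BackgroundModel, a: str, b: str, t: int) -> float:
    """Entry (a, b) of the t-th power of the transition matrix.

    For order 0 this equals mu(b) for every t (memoryless chain).
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    ia, ib = LETTER_CODE[a.upper()], LETTER_CODE[b.upper()]
    return float(model.power(t)[ia, ib])


def save_model(model: BackgroundModel, path: str | Path) -> None:
    """Write a model as a small plain-text key-value file."""
    lines = [f"order\t{model.order}", f"pseudocount\t{float(model.pseudocount):.17g}"]
    for i, a in enumerate(ALPHABET):
        lines.append(f"mu_{a}\t{float(model.base_probs[i]):.17g}")
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            lines.append(f"pi_{a}{b}\t{float(model.transitions[i, j]):.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> BackgroundModel:
    """Read a model written by :func:`save_model`."""
    kv: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, value = line.split("\t")
        kv[key] = value
    base = np.array([float(kv[f"mu_{a}"]) for a in ALPHABET])
    trans = np.array(
        [[float(kv[f"pi_{a}{b}"]) for b in ALPHABET] for a in ALPHABET]
    )
    return BackgroundModel(int(kv["order"]), base, trans, float(kv["pseudocount"]))
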
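"""Pairwise alignment-free similarity measures.

Fixed-resolution statistics over the k-mer count vectors A_w, B_w of two
sequences:

    D2   = sum_w A_w B_w
    D2s  = sum_w  ~A_w ~B_w / sqrt(~A_w^2 + ~B_w^2)
    D2*  = sum_w  ~A_w ~B_w / ((n - k + 1) p_w)

with ~A_w = A_w - (l_A - k + 1) p_w^A the count centred under the
sequence's own background model.  Their multi-resolution analogues replace
counts by simple entropies SE_w:

    EP2  = sum_w A_SE_w B_SE_w
    EP2* = sum_w (A_SE_w - E[A_SE_w]) (B_SE_w - E[B_SE_w]) / V_w

where expectations and variances are the exact entropy moments of each
sequence under its own model.  The sums run over the full universe of 4**L
words (centred terms are non-zero even for absent words); in
reverse-complement mode they run over strand classes {w, rc(w)}, each
class contributing the maximum entropy of its two members together with
the moments of the word attaining that maximum.

Conventions for quantities the single-sequence formulas leave open with
two sequences of unequal length: p_w in the D2* denominator is the
geometric mean sqrt(p_w^A p_w^B), n the geometric mean of the lengths, and
the EP2* denominator V_w is sqrt(Var_A[SE_w] Var_B[SE_w]) ("exact"
convention) or sqrt(E_A[SE_w] E_B[SE_w]) ("poisson" convention, the
mean-for-variance approximation under which EP2* at a degenerate kernel
reduces to D2*).  All measures are symmetric in their two arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd

from entroprof.background import BackgroundModel, estimate_model
from entroprof.entropy import all_simple_entropies, canonical_classes
from entroprof.kmers import build_index
from entroprof.moments import _letters_matrix, batch_entropy_moments
from entroprof.sequence import Sequence
from entroprof.weights import WeightScheme, gaussian_weights

MEASURES = ("d2", "d2s", "d2star", "ep2", "ep2star")


def all_word_probabilities(model: BackgroundModel, k: int) -> np.ndarray:
    """mu(w) for every length-k word, indexed by word code."""
    W = _letters_matrix(k)
    p = model.base_probs[W[:, 0]].astype(float)
    for j in range(1, k):
        p = p * model.transitions[W[:, j - 1], W[:, j]]
    return p


# ---------------------------------------------------------------------------
# per-sequence summaries reused across pairs
# ---------------------------------------------------------------------------


@dataclass
class SequenceProfile:
    """Everything a pairwise score needs from one sequence."""

    id: str
    l: int
    k: int
    counts: np.ndarray  # (4**k,) k-mer counts
    probs: Optional[np.ndarray] = None  # (4**k,) word probabilities
    se: Optional[np.ndarray] = None  # (4**k,) simple entropies
    exp: Optional[np.ndarray] = None  # (4**k,) E[SE_w]
    var: Optional[np.ndarray] = None  # (4**k,) Var[SE_w]

    @property
    def centred(self) -> np.ndarray:
        return self.counts - (self.l - self.k + 1) * self.probs


def sequence_profile(
    seq: Sequence,
    k: int,
    weights: Optional[WeightScheme] = None,
    order: int = 1,
    pseudocount: float = 1.0,
    include_nonoverlap: bool = False,
    need_model: bool = True,
    need_moments: bool = False,
) -> SequenceProfile:
    """Counts, entropies and entropy moments of one sequence at resolution k."""
    if k < 1 or k > seq.l:
        raise ValueError(f"resolution {k} outside 1..{seq.l} for {seq.id!r}")
    index = build_index(seq, k)
    prof = SequenceProfile(seq.id, seq.l, k, index.dense(k).astype(float))
    if need_model or need_moments:
        model = estimate_model(seq, order=order, pseudocount=pseudocount)
        prof.probs = all_word_probabilities(model, k)
    if weights is not None:
        prof.se = all_simple_entropies(index, weights)
        if need_moments:
            prof.exp, prof.var = batch_entropy_moments(
                model, weights, seq.l, include_nonoverlap
            )
    return prof


def _class_select(
    reps: np.ndarray, partners: np.ndarray, prof: SequenceProfile
) -> Dict[str, np.ndarray]:
    """Collapse per-word arrays to strand classes via the max-entropy rule."""
    fwd, rev = prof.se[reps], prof.se[partners]
    take_fwd = fwd >= rev  # ties go to the canonical representative
    out = {"se": np.where(take_fwd, fwd, rev)}
    if prof.exp is not None:
        out["exp"] = np.where(take_fwd, prof.exp[reps], prof.exp[partners])
    if prof.var is not None:
        out["var"] = np.where(take_fwd, prof.var[reps], prof.var[partners])
    return out


# ---------------------------------------------------------------------------
# fixed-resolution measures
# ---------------------------------------------------------------------------


def _check_k(seqA: Sequence, seqB: Sequence, k: int) -> None:
    if k < 1 or k > min(seqA.l, seqB.l):
        raise ValueError(
            f"k={k} outside 1..min(l_A, l_B)={min(seqA.l, seqB.l)}"
        )


def d2(seqA: Sequence, seqB: Sequence, k: int) -> float:
    """Inner product of the k-mer count vectors."""
    _check_k(seqA, seqB, k)
    a = build_index(seqA, k).dense(k)
    b = build_index(seqB, k).dense(k)
    return float(a @ b)


def d2s(
    seqA: Sequence,
    seqB: Sequence,
    k: int,
    order: int = 1,
    pseudocount: float = 1.0,
) -> float:
    """Self-standardised D2: terms ~A ~B / sqrt(~A^2 + ~B^2)."""
    _check_k(seqA, seqB, k)
    pa = sequence_profile(seqA, k, order=order, pseudocount=pseudocount)
    pb = sequence_profile(seqB, k, order=order, pseudocount=pseudocount)
    ca, cb = pa.centred, pb.centred
    den = np.sqrt(ca**2 + cb**2)
    mask = den > 0
    return float((ca[mask] * cb[mask] / den[mask]).sum())


def d2star(
    seqA: Sequence,
    seqB: Sequence,
    k: int,
    order: int = 1,
    pseudocount: float = 1.0,
) -> float:
    """Background-standardised D2: terms ~A ~B / ((n - k + 1) p_w).

    With unequal lengths, n is the geometric mean of the lengths and p_w
    the geometric mean of the two per-sequence word probabilities.
    """
    _check_k(seqA, seqB, k)
    pa = sequence_profile(seqA, k, order=order, pseudocount=pseudocount)
    pb = sequence_profile(seqB, k, order=order, pseudocount=pseudocount)
    n = float(np.sqrt(seqA.l * seqB.l))
    den = (n - k + 1) * np.sqrt(pa.probs * pb.probs)
    mask = den > 0
    return float((pa.centred[mask] * pb.centred[mask] / den[mask]).sum())


# ---------------------------------------------------------------------------
# multi-resolution measures
# ---------------------------------------------------------------------------


def ep2(
    seqA: Sequence,
    seqB: Sequence,
    L: int,
    sigma: float,
    revcomp: bool = False,
) -> float:
    """Inner product of the simple-entropy vectors (strand classes if
    ``revcomp``)."""
    _check_k(seqA, seqB, L)
    weights = gaussian_weights(L, sigma)
    pa = sequence_profile(seqA, L, weights=weights, need_model=False)
    pb = sequence_profile(seqB, L, weights=weights, need_model=False)
    if not revcomp:
        return float(pa.se @ pb.se)
    reps, partners = canonical_classes(L)
    sa = _class_select(reps, partners, pa)["se"]
    sb = _class_select(reps, partners, pb)["se"]
    return float(sa @ sb)


def ep2star(
    seqA: Sequence,
    seqB: Sequence,
    L: int,
    sigma: float,
    order: int = 1,
    revcomp: bool = False,
    include_nonoverlap: bool = False,
    variance: str = "exact",
    pseudocount: float = 1.0,
) -> float:
    """Entropy analogue of D2*: exact-moment-standardised inner product."""
    _check_k(seqA, seqB, L)
    weights = gaussian_weights(L, sigma)
    kwargs = dict(
        weights=weights,
        order=order,
        pseudocount=pseudocount,
        include_nonoverlap=include_nonoverlap,
        need_moments=True,
    )
    pa = sequence_profile(seqA, L, **kwargs)
    pb = sequence_profile(seqB, L, **kwargs)
    return _ep2star_from_profiles(pa, pb, L, revcomp, variance)


def _ep2star_from_profiles(
    pa: SequenceProfile,
    pb: SequenceProfile,
    L: int,
    revcomp: bool,
    variance: str,
) -> float:
    if variance not in ("exact", "poisson"):
        raise ValueError(f"variance must be 'exact' or 'poisson', got {variance!r}")
    if revcomp:
        reps, partners = canonical_classes(L)
        a = _class_select(reps, partners, pa)
        b = _class_select(reps, partners, pb)
        se_a, exp_a, var_a = a["se"], a["exp"], a["var"]
        se_b, exp_b, var_b = b["se"], b["exp"], b["var"]
    else:
        se_a, exp_a, var_a = pa.se, pa.exp, pa.var
        se_b, exp_b, var_b = pb.se, pb.exp, pb.var
    num = (se_a - exp_a) * (se_b - exp_b)
    if variance == "exact":
        den = np.sqrt(var_a * var_b)
    else:
        den = np.sqrt(exp_a * exp_b)
    mask = den > 0
    return float((num[mask] / den[mask]).sum())


# ---------------------------------------------------------------------------
# all-pairs scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreMatrix:
    """Symmetric matrix of pairwise scores with its provenance."""

    measure: str
    ids: List[str]
    matrix: np.ndarray
    params: Dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered off-diagonal pair."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {
                        "idA": self.ids[i],
                        "idB": self.ids[j],
                        "measure": self.measure,
                        "resolution": self.params.get("k", self.params.get("L")),
                        "score": self.matrix[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def pair_scores(self) -> np.ndarray:
        """Off-diagonal upper-triangle scores as a flat array."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]


def pairwise_matrix(
    seqs: TypingSequence[Sequence],
    measure: str,
    k: Optional[int] = None,
    L: Optional[int] = None,
    sigma: float = 0.7,
    order: int = 1,
    revcomp: bool = False,
    include_nonoverlap: bool = False,
    variance: str = "exact",
    pseudocount: float = 1.0,
) -> ScoreMatrix:
    """All unordered pair scores for one measure, per-sequence work shared.

    ``k`` names the resolution of the fixed-length measures, ``L`` that of
    the entropy measures; either may be given (they are aliases here).
    The diagonal holds self-comparison scores and is reported for
    completeness but excluded from :meth:`ScoreMatrix.pair_scores`.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; valid: {MEASURES}")
    if variance not in ("exact", "poisson"):
        raise ValueError(f"variance must be 'exact' or 'poisson', got {variance!r}")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    res = k if k is not None else L
    if res is None:
        raise ValueError("resolution (k or L) is required")
    n = len(seqs)
    entropic = measure in ("ep2", "ep2star")
    weights = gaussian_weights(res, sigma) if entropic else None
    profiles = [
        sequence_profile(
            s,
            res,
            weights=weights,
            order=order,
            pseudocount=pseudocount,
            include_nonoverlap=include_nonoverlap,
            need_model=measure in ("d2s", "d2star", "ep2star"),
            need_moments=measure == "ep2star",
        )
        for s in seqs
    ]
    if entropic and revcomp:
        reps, partners = canonical_classes(res)
        selections = [_class_select(reps, partners, p) for p in profiles]

    def score(i: int, j: int) -> float:
        pa, pb = profiles[i], profiles[j]
        if measure == "d2":
            return float(pa.counts @ pb.counts)
        if measure == "d2s":
            ca, cb = pa.centred, pb.centred
            den = np.sqrt(ca**2 + cb**2)
            m = den > 0
            return float((ca[m] * cb[m] / den[m]).sum())
        if measure == "d2star":
            nn = float(np.sqrt(pa.l * pb.l))
            den = (nn - res + 1) * np.sqrt(pa.probs * pb.probs)
            m = den > 0
            return float((pa.centred[m] * pb.centred[m] / den[m]).sum())
        if measure == "ep2":
            if revcomp:
                return float(selections[i]["se"] @ selections[j]["se"])
            return float(pa.se @ pb.se)
        # ep2star
        if revcomp:
            a, b = selections[i], selections[j]
            num = (a["se"] - a["exp"]) * (b["se"] - b["exp"])
            den = (
                np.sqrt(a["var"] * b["var"])
                if variance == "exact"
                else np.sqrt(a["exp"] * b["exp"])
            )
            m = den > 0
            return float((num[m] / den[m]).sum())
        return _ep2star_from_profiles(pa, pb, res, False, variance)

    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            matrix[i, j] = matrix[j, i] = score(i, j)
    params: Dict[str, object] = {
        "k" if not entropic else "L": res,
        "order": order,
        "pseudocount": pseudocount,
    }
    if entropic:
        params.update(sigma=sigma, revcomp=revcomp)
    if measure == "ep2star":
        params.update(
            include_nonoverlap=include_nonoverlap, variance=variance
        )
    return ScoreMatrix(measure, [s.id for s in seqs], matrix, params)
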
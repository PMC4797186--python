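"""Exact moments of overlapping word counts and of simple entropies.

Under a stationary order-0 or order-1 Markov background, the count of a
word and the counts of its suffixes are strongly coupled: occurrences may
overlap, and a word occurring forces every suffix to occur at the aligned
offset.  This module provides the exact expectation and variance of the
simple entropy SE_w by assembling, suffix pair by suffix pair, the exact
covariance matrix of the suffix counts:

* expectation:   E[c_{w,k}] = (l - k + 1) mu(s_{w,k});
* same length:   Var[c_{w,k}] sums a Bernoulli term, partial self-overlap
  terms governed by the word's autocorrelation, and (optionally) terms for
  disjoint occurrence pairs, which vanish only for order-0 models;
* nested pair:   Cov[c_{w'}, c_{w''}] for w'' a proper suffix of w', found
  by classifying every ordered position pair by its shift d: the shorter
  word inside the longer one (including the start-aligned d = 0 case),
  straddling its right end, hanging off its left end, or disjoint.

Every shift coefficient is the exact number of position pairs at which
both occurrence indicators can be non-zero: a word of length k can only
start at positions 1..l-k+1, so the pair count for shift d is
min(l-k'+1, l-k''+1-d) for rightward shifts and l-k'+1-d for leftward
ones.  These counts are validated against brute-force enumeration over all
4**l sequences in the test suite.

Dropping the disjoint ("non-overlap") terms assumes occurrences separated
by arbitrary background are independent; the error this introduces decays
as the sequence grows and is the conventional choice when scoring.  With
the terms dropped, an assembled variance can come out marginally negative
for corner cases; it is then clipped to VAR_FLOOR with a warning.

The scalar functions are the reference implementation; the batch helpers
recompute the same quantities for all 4**L words at once with vectorised
array operations and are cross-checked against the scalar path in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np

from entroprof.background import BackgroundModel, word_probability
from entroprof.sequence import LETTER_CODE
from entroprof.weights import WeightScheme

logger = logging.getLogger(__name__)

#: floor applied to assembled entropy variances that come out non-positive
VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# overlap indicators
# ---------------------------------------------------------------------------


def overlap_indicator(w: str, u: int) -> int:
    """1 iff the length-u suffix of ``w`` equals its length-u prefix."""
    if u < 0 or u > len(w):
        raise ValueError(f"u={u} outside 0..{len(w)}")
    if u == 0:
        return 1
    return int(w[len(w) - u :] == w[:u])


def overlap_indicator_left(w_short: str, w_long: str, u: int) -> int:
    """1 iff the length-u suffix of ``w_short`` equals the length-u prefix
    of ``w_long`` (the shorter word hangs off the left end of the longer)."""
    if u < 0 or u > min(len(w_short), len(w_long)):
        raise ValueError(f"u={u} outside 0..{min(len(w_short), len(w_long))}")
    if u == 0:
        return 1
    return int(w_short[len(w_short) - u :] == w_long[:u])


def overlap_indicator_right(w_long: str, w_short: str, u: int) -> int:
    """Overlap indicator for the shorter word shifted right by len(w_long)-u.

    For u < len(w_short) the shorter word straddles the right end of the
    longer: match its length-u prefix against the length-u suffix of the
    longer word.  For u >= len(w_short) the shorter word lies entirely
    inside the longer at the aligned offset len(w_long) - u (0-based).
    """
    k_long, k_short = len(w_long), len(w_short)
    if u < 0 or u > k_long:
        raise ValueError(f"u={u} outside 0..{k_long}")
    if u < k_short:
        if u == 0:
            return 1
        return int(w_long[k_long - u :] == w_short[:u])
    start = k_long - u
    return int(w_long[start : start + k_short] == w_short)


# ---------------------------------------------------------------------------
# expectations
# ---------------------------------------------------------------------------


def expected_count(model: BackgroundModel, w: str, l: int) -> float:
    """E[c_w] = (l - |w| + 1) mu(w); zero when the word does not fit."""
    k = len(w)
    if k > l:
        return 0.0
    return (l - k + 1) * word_probability(model, w)


def expected_entropy(
    model: BackgroundModel, w: str, weights: WeightScheme, l: int
) -> float:
    """E[SE_w] = sum_k a_k E[c_{w,k}] / sum_k a_k for |w| = L."""
    if len(w) != weights.L:
        raise ValueError(f"expected a word of length {weights.L}, got {w!r}")
    acc = 0.0
    for k in range(1, weights.L + 1):
        acc += weights.values[k - 1] * expected_count(model, w[-k:], l)
    return acc / weights.total


# ---------------------------------------------------------------------------
# variance and covariance of counts
# ---------------------------------------------------------------------------


def _transition_product(model: BackgroundModel, w: str, start: int) -> float:
    """prod_{j=start+1}^{|w|} pi(w_{j-1}, w_j) with ``start`` 1-based."""
    idx = [LETTER_CODE[a] for a in w]
    p = 1.0
    for j in range(start, len(w)):
        p *= float(model.transitions[idx[j - 1], idx[j]])
    return p


def count_variance(
    model: BackgroundModel, w: str, l: int, include_nonoverlap: bool = True
) -> float:
    """Exact variance of the occurrence count of ``w`` in a length-l chain.

    Sums the per-position Bernoulli variance, the partial self-overlap
    terms (shifts d = 1..|w|-1, gated by the autocorrelation of ``w``) and,
    when ``include_nonoverlap``, the disjoint-occurrence terms that couple
    positions more than |w| apart through the chain's memory.
    """
    w = w.upper()
    k = len(w)
    if k > l:
        return 0.0
    mu = word_probability(model, w)
    var = (l - k + 1) * mu * (1.0 - mu)
    for d in range(1, k):
        coef = l - k + 1 - d
        if coef <= 0:
            continue
        u = k - d
        eps = overlap_indicator(w, u)
        joint = eps * _transition_product(model, w, u) if eps else 0.0
        var += 2.0 * mu * coef * (joint - mu)
    if include_nonoverlap:
        first = LETTER_CODE[w[0]]
        last = LETTER_CODE[w[-1]]
        mu_first = float(model.base_probs[first])
        for t in range(1, l - 2 * k + 2):
            coef = l - 2 * k + 2 - t
            pt = float(model.power(t)[last, first])
            var += 2.0 * mu * mu * coef * (pt / mu_first - 1.0)
    return var


def count_covariance(
    model: BackgroundModel,
    w_long: str,
    w_short: str,
    l: int,
    include_nonoverlap: bool = True,
) -> float:
    """Exact covariance of the counts of a word and one of its suffixes.

    ``w_short`` must be a proper suffix of ``w_long`` (arguments may be
    given in either order; the value is symmetric).  Position pairs are
    classified by the shift d of the shorter word relative to the longer:

    * d = 0..k'-k'': the shorter word sits inside the longer one;
    * k'-k'' < d < k': it straddles the longer word's right end;
    * 1 <= d < k'' leftwards: it hangs off the longer word's left end;
    * larger shifts: disjoint occurrences (``include_nonoverlap`` only).
    """
    w_long, w_short = w_long.upper(), w_short.upper()
    if len(w_short) > len(w_long):
        w_long, w_short = w_short, w_long
    k1, k2 = len(w_long), len(w_short)
    if k1 == k2 or not w_long.endswith(w_short):
        raise ValueError(
            f"{w_short!r} is not a proper suffix of {w_long!r}"
        )
    if k1 > l:
        return 0.0
    mu1 = word_probability(model, w_long)
    mu2 = word_probability(model, w_short)
    n1 = l - k1 + 1
    cov = 0.0

    # zero shift and rightward shifts of the shorter word
    for d in range(0, k1):
        coef = min(n1, l - k2 + 1 - d)
        if coef <= 0:
            continue
        u = k1 - d
        eps = overlap_indicator_right(w_long, w_short, u)
        if not eps:
            joint = 0.0
        elif d <= k1 - k2:
            joint = mu1  # shorter word fully inside the longer one
        else:
            joint = mu1 * _transition_product(model, w_short, u)
        cov += coef * (joint - mu1 * mu2)

    # leftward shifts: the shorter word starts before the longer one
    for d in range(1, k2):
        coef = n1 - d
        if coef <= 0:
            continue
        u = k2 - d
        eps = overlap_indicator_left(w_short, w_long, u)
        joint = eps * mu2 * _transition_product(model, w_long, u) if eps else 0.0
        cov += coef * (joint - mu1 * mu2)

    if include_nonoverlap:
        first1, first2 = LETTER_CODE[w_long[0]], LETTER_CODE[w_short[0]]
        last = LETTER_CODE[w_long[-1]]  # both words end with the same letter
        mu_f1 = float(model.base_probs[first1])
        mu_f2 = float(model.base_probs[first2])
        # shorter word entirely to the right of the longer one
        for d in range(k1, l - k2 + 1):
            coef = l - k2 + 1 - d
            if coef <= 0:
                continue
            t = d - k1 + 1
            pt = float(model.power(t)[last, first2])
            cov += coef * mu1 * mu2 * (pt / mu_f2 - 1.0)
        # shorter word entirely to the left of the longer one
        for d in range(k2, l - k1 + 1):
            coef = n1 - d
            if coef <= 0:
                continue
            t = d - k2 + 1
            pt = float(model.power(t)[last, first1])
            cov += coef * mu1 * mu2 * (pt / mu_f1 - 1.0)
    return cov


# ---------------------------------------------------------------------------
# variance of the simple entropy
# ---------------------------------------------------------------------------


@dataclass
class WordMoments:
    """Exact moments of SE_w for one word under one background model."""

    word: str
    l: int
    expectation: float
    variance: float
    suffix_expectations: np.ndarray  # E[c_{w,k}], k = 1..L
    covariance: np.ndarray  # (L, L) matrix Cov[c_{w,k'}, c_{w,k''}]
    include_nonoverlap: bool


def entropy_variance(
    model: BackgroundModel,
    w: str,
    weights: WeightScheme,
    l: int,
    include_nonoverlap: bool = True,
) -> float:
    """Var[SE_w] = a' C a / (sum a)^2 with C the suffix-count covariance."""
    return word_moments(model, w, weights, l, include_nonoverlap).variance


def word_moments(
    model: BackgroundModel,
    w: str,
    weights: WeightScheme,
    l: int,
    include_nonoverlap: bool = True,
) -> WordMoments:
    """Assemble E[SE_w], Var[SE_w] and the underlying covariance matrix."""
    w = w.upper()
    L = weights.L
    if len(w) != L:
        raise ValueError(f"expected a word of length {L}, got {w!r}")
    cov = np.zeros((L, L))
    exp_counts = np.zeros(L)
    for k in range(1, L + 1):
        exp_counts[k - 1] = expected_count(model, w[-k:], l)
        cov[k - 1, k - 1] = count_variance(model, w[-k:], l, include_nonoverlap)
    for k1 in range(2, L + 1):
        for k2 in range(1, k1):
            c = count_covariance(model, w[-k1:], w[-k2:], l, include_nonoverlap)
            cov[k1 - 1, k2 - 1] = cov[k2 - 1, k1 - 1] = c
    a = weights.values
    expectation = float(a @ exp_counts / weights.total)
    variance = float(a @ cov @ a / weights.total**2)
    if variance < VAR_FLOOR:
        logger.warning(
            "Var[SE_%s] = %.3e below floor; clipped to %.0e "
            "(non-overlap terms %s)",
            w,
            variance,
            VAR_FLOOR,
            "on" if include_nonoverlap else "off",
        )
        variance = VAR_FLOOR
    return WordMoments(
        w, l, expectation, variance, exp_counts, cov, include_nonoverlap
    )


# ---------------------------------------------------------------------------
# batch computation over the full word universe
# ---------------------------------------------------------------------------


def _letters_matrix(L: int) -> np.ndarray:
    """(4**L, L) matrix of letter codes of every length-L word."""
    codes = np.arange(4**L, dtype=np.int64)
    return np.stack(
        [(codes // 4 ** (L - 1 - j)) % 4 for j in range(L)], axis=1
    )


def _disjoint_kernels(model: BackgroundModel, horizons: Iterable[int]) -> Dict[int, np.ndarray]:
    """F(T) = sum_{t=1}^{T} (T + 1 - t) pi^t, for each requested horizon T.

    F contracts the whole disjoint-occurrence sum into one 4x4 matrix per
    horizon: the coefficient T + 1 - t is the number of position pairs at
    gap t, so a single lookup F[a, b] replaces the sum over t.
    """
    wanted = sorted({T for T in horizons if T >= 1})
    out: Dict[int, np.ndarray] = {}
    if not wanted:
        return out
    pi = model.transitions
    power = np.eye(4)
    cum = np.zeros((4, 4))
    F = np.zeros((4, 4))
    for t in range(1, wanted[-1] + 1):
        power = power @ pi
        cum += power  # cum = S(t) = sum_{s<=t} pi^s
        F += cum  # F(t) = F(t-1) + S(t)
        if t in wanted:
            out[t] = F.copy()
    return out


def batch_entropy_moments(
    model: BackgroundModel,
    weights: WeightScheme,
    l: int,
    include_nonoverlap: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """E[SE_w] and Var[SE_w] for every length-L word, indexed by word code.

    Vectorised re-derivation of :func:`word_moments` across the full
    universe of 4**L words; equality with the scalar path is asserted in
    the test suite.  Variances below VAR_FLOOR are clipped (one summary
    warning per call).
    """
    L = weights.L
    N = 4**L
    a = weights.values
    W = _letters_matrix(L)
    base = model.base_probs
    trans = model.transitions[W[:, :-1], W[:, 1:]] if L > 1 else np.zeros((N, 0))
    # rcp[:, j] = product of transition columns j..L-2 (empty product = 1);
    # the product of the last m transitions of any suffix is rcp[:, L-1-m]
    rcp = np.ones((N, L))
    for j in range(L - 2, -1, -1):
        rcp[:, j] = rcp[:, j + 1] * trans[:, j]
    mu_suf = [np.zeros(N)]  # 1-based: mu_suf[k] = mu of the length-k suffix
    for k in range(1, L + 1):
        mu_suf.append(base[W[:, L - k]] * rcp[:, L - k])

    exp_acc = np.zeros(N)
    for k in range(1, L + 1):
        if k <= l:
            exp_acc += a[k - 1] * (l - k + 1) * mu_suf[k]
    expectation = exp_acc / weights.total

    if include_nonoverlap:
        horizons = [l - 2 * k + 1 for k in range(1, L + 1)]
        horizons += [
            l - k1 - k2 + 1 for k1 in range(2, L + 1) for k2 in range(1, k1)
        ]
        F = _disjoint_kernels(model, horizons)

    var_acc = np.zeros(N)
    for k in range(1, L + 1):
        if k > l:
            continue
        mu = mu_suf[k]
        v = (l - k + 1) * mu * (1.0 - mu)
        for d in range(1, k):
            coef = l - k + 1 - d
            if coef <= 0:
                continue
            u = k - d
            eps = (W[:, L - u :] == W[:, L - k : L - k + u]).all(axis=1)
            v = v + 2.0 * mu * coef * (eps * rcp[:, L - 1 - d] - mu)
        if include_nonoverlap:
            T = l - 2 * k + 1
            if T >= 1:
                ratio = F[T][W[:, L - 1], W[:, L - k]] / base[W[:, L - k]]
                v = v + 2.0 * mu * mu * (ratio - T * (T + 1) / 2.0)
        var_acc += a[k - 1] ** 2 * v

    for k1 in range(2, L + 1):
        if k1 > l:
            continue
        for k2 in range(1, k1):
            mu1, mu2 = mu_suf[k1], mu_suf[k2]
            n1 = l - k1 + 1
            cov = np.zeros(N)
            for d in range(0, k1):
                coef = min(n1, l - k2 + 1 - d)
                if coef <= 0:
                    continue
                if d <= k1 - k2:
                    eps = (
                        W[:, L - k1 + d : L - k1 + d + k2] == W[:, L - k2 :]
                    ).all(axis=1)
                    joint = eps * mu1
                else:
                    u = k1 - d  # 0 < u < k2
                    eps = (W[:, L - u :] == W[:, L - k2 : L - k2 + u]).all(axis=1)
                    joint = eps * mu1 * rcp[:, L - 1 - (k2 - u)]
                cov = cov + coef * (joint - mu1 * mu2)
            for d in range(1, k2):
                coef = n1 - d
                if coef <= 0:
                    continue
                u = k2 - d
                eps = (W[:, L - u :] == W[:, L - k1 : L - k1 + u]).all(axis=1)
                joint = eps * mu2 * rcp[:, L - 1 - (k1 - u)]
                cov = cov + coef * (joint - mu1 * mu2)
            if include_nonoverlap:
                T = l - k1 - k2 + 1
                if T >= 1:
                    tri = T * (T + 1) / 2.0
                    r_right = F[T][W[:, L - 1], W[:, L - k2]] / base[W[:, L - k2]]
                    r_left = F[T][W[:, L - 1], W[:, L - k1]] / base[W[:, L - k1]]
                    cov = cov + mu1 * mu2 * (r_right + r_left - 2.0 * tri)
            var_acc += 2.0 * a[k1 - 1] * a[k2 - 1] * cov

    variance = var_acc / weights.total**2
    low = variance < VAR_FLOOR
    if np.any(low):
        logger.warning(
            "%d of %d Var[SE_w] values below floor; clipped to %.0e",
            int(low.sum()),
            N,
            VAR_FLOOR,
        )
        variance = np.where(low, VAR_FLOOR, variance)
    return expectation, variance
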
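"""Synthetic benchmark data: random backgrounds and implanted motifs.

The benchmark protocol builds two equal-size sets of sequences.  The
*negative* set is background only — letter-by-letter draws from an M0/M1
model, or windows cut from a user-supplied background pool (e.g. real
intergenic sequence).  The *positive* set is, by default, the very same
background sequences with short motifs implanted, so the comparison is
paired and any separation between the sets is attributable to the
implanted signal alone.

Implantation follows a pattern-transfer scheme: scanning left to right,
each eligible position independently receives an implant with probability
``insertion_prob``; an implant overwrites the next |m| letters with a
motif m drawn uniformly from the motif set and the scan jumps past it, so
implants never overlap and the sequence length never changes.  With
motifs of a single common length this is the fixed-length variant; with
motifs of several lengths it is the revised, variable-length variant.

All randomness flows from a single seed through ``numpy``'s SeedSequence
spawning, so every generated set is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence as TypingSequence, Tuple

import numpy as np
import pandas as pd

from entroprof.background import BackgroundModel
from entroprof.sequence import ALPHABET, Sequence


@dataclass(frozen=True)
class ImplantSpec:
    """Motif set and per-position insertion probability."""

    motifs: Tuple[str, ...]
    insertion_prob: float
    mode: str = "revised"  # "fixed" requires equal-length motifs

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif set must be non-empty")
        motifs = tuple(m.upper() for m in self.motifs)
        for m in motifs:
            if not m or set(m) - set(ALPHABET):
                raise ValueError(f"motif {m!r} must be a non-empty ACGT word")
        object.__setattr__(self, "motifs", motifs)
        if not 0.0 <= self.insertion_prob <= 1.0:
            raise ValueError(
                f"insertion_prob must be in [0, 1], got {self.insertion_prob}"
            )
        if self.mode not in ("fixed", "revised"):
            raise ValueError(f"mode must be 'fixed' or 'revised', got {self.mode!r}")
        if self.mode == "fixed" and len({len(m) for m in motifs}) != 1:
            raise ValueError("fixed-length mode requires equal-length motifs")


def random_sequence(
    model: BackgroundModel,
    length: int,
    seed: int | np.random.Generator,
    id: str = "random",
) -> Sequence:
    """Sample a sequence from the model: first letter from mu, rest from pi."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    letters = np.empty(length, dtype=np.int64)
    letters[0] = rng.choice(4, p=model.base_probs)
    if model.order == 0:
        if length > 1:
            letters[1:] = rng.choice(4, size=length - 1, p=model.base_probs)
    else:
        # cumulative rows let the whole chain run on one uniform draw block
        cum = np.cumsum(model.transitions, axis=1)
        u = rng.random(length - 1)
        for i in range(1, length):
            letters[i] = np.searchsorted(cum[letters[i - 1]], u[i - 1], side="right")
    residues = "".join(ALPHABET[c] for c in letters)
    return Sequence(id, residues)


def _m0_for_gc(gc: float) -> BackgroundModel:
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BackgroundModel(0, base, np.tile(base, (4, 1)), pseudocount=0.0)


def synthetic_genome_pool(
    n_records: int,
    record_length: int,
    seed: int | np.random.Generator,
    gc_range: Tuple[float, float] = (0.3, 0.7),
    id_prefix: str = "contig",
) -> List[Sequence]:
    """Synthetic stand-in for a real genomic background pool.

    Real intergenic sequence is compositionally heterogeneous: windows cut
    from different locations differ markedly in GC content, and that
    between-window variation — not any shared motif — dominates raw
    word-count statistics.  This generator emulates exactly that feature:
    each record is an i.i.d. (M0) sequence whose GC content is drawn
    uniformly from ``gc_range``, with strand symmetry within each record.
    It does not emulate repeats, local motif structure or long-range
    correlations of real genomes.
    """
    if n_records < 1 or record_length < 1:
        raise ValueError("n_records and record_length must be positive")
    lo, hi = gc_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError(f"gc_range must satisfy 0 < lo <= hi < 1, got {gc_range}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_records):
        gc = float(rng.uniform(lo, hi))
        out.append(
            Sequence(
                f"{id_prefix}_{i:03d}",
                random_sequence(_m0_for_gc(gc), record_length, rng).residues,
            )
        )
    return out


def sample_background_windows(
    pool: TypingSequence[Sequence],
    window: int,
    n: int,
    seed: int | np.random.Generator,
) -> List[Sequence]:
    """Draw n windows uniformly over all valid N-free (sequence, offset) slots."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    rng = np.random.default_rng(seed)
    slots: List[Tuple[int, int]] = []
    for si, seq in enumerate(pool):
        if seq.l < window:
            continue
        valid = seq.codes() >= 0
        # a window starting at offset o is usable iff it contains no N
        ok = np.ones(seq.l - window + 1, dtype=bool)
        run = np.convolve(valid.astype(int), np.ones(window, dtype=int), "valid")
        ok &= run == window
        slots.extend((si, int(o)) for o in np.nonzero(ok)[0])
    if not slots:
        raise ValueError(f"no N-free window of length {window} in the pool")
    picks = rng.integers(0, len(slots), size=n)
    out = []
    for j, p in enumerate(picks):
        si, o = slots[p]
        out.append(
            Sequence(f"{pool[si].id}:{o + 1}-{o + window}", pool[si].residues[o : o + window])
        )
    return out


def implant_motifs(
    seq: Sequence,
    spec: ImplantSpec,
    seed: int | np.random.Generator,
) -> Tuple[Sequence, List[Tuple[int, str]]]:
    """Implant motifs into a sequence; returns the new sequence and a log.

    Eligible positions are those where the longest motif still fits, so
    every accepted implant fits whole.  The log records (position, motif)
    with 1-based positions; output length equals input length.
    """
    rng = np.random.default_rng(seed)
    max_len = max(len(m) for m in spec.motifs)
    if max_len >= seq.l:
        raise ValueError("every motif must be shorter than the sequence")
    residues = list(seq.residues)
    log: List[Tuple[int, str]] = []
    i = 0
    last_eligible = seq.l - max_len
    while i <= last_eligible:
        if spec.insertion_prob > 0 and rng.random() < spec.insertion_prob:
            m = spec.motifs[rng.integers(0, len(spec.motifs))]
            residues[i : i + len(m)] = m
            log.append((i + 1, m))
            i += len(m)
        else:
            i += 1
    return Sequence(seq.id, "".join(residues)), log


def build_experiment_sets(
    n: int,
    length: int,
    spec: ImplantSpec,
    seed: int,
    model: Optional[BackgroundModel] = None,
    pool: Optional[TypingSequence[Sequence]] = None,
    gc_range: Optional[Tuple[float, float]] = None,
    paired: bool = True,
) -> Tuple[List[Sequence], List[Sequence], pd.DataFrame]:
    """Build negative (background) and positive (implanted) sequence sets.

    Background comes from exactly one of ``model`` (random chains from one
    shared model), ``pool`` (windows cut from supplied sequences), or
    ``gc_range`` (each sequence drawn i.i.d. with its own GC content
    sampled uniformly from the range — the compositionally heterogeneous
    stand-in for genomic windows, see :func:`synthetic_genome_pool`).
    With ``paired`` (the default)
    the positive set implants motifs into copies of the negative
    sequences; with ``paired=False`` the positive set is built on an
    independent background draw of its own, which is the right null when
    the insertion probability is zero.

    Returns (negative set, positive set, implant log) where the log has
    columns (id, position, motif), positions 1-based.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 sequences per set, got {n}")
    sources = sum(x is not None for x in (model, pool, gc_range))
    if sources != 1:
        raise ValueError("exactly one of model, pool or gc_range must be given")
    root = np.random.SeedSequence(seed)
    bg_ss, pos_bg_ss, implant_ss = root.spawn(3)

    def draw_background(ss: np.random.SeedSequence, tag: str) -> List[Sequence]:
        if pool is not None:
            drawn = sample_background_windows(pool, length, n, np.random.default_rng(ss))
            return [Sequence(f"{tag}_{i:03d}", s.residues) for i, s in enumerate(drawn)]
        out = []
        for i, child in enumerate(ss.spawn(n)):
            rng = np.random.default_rng(child)
            m = model if model is not None else _m0_for_gc(float(rng.uniform(*gc_range)))
            out.append(Sequence(f"{tag}_{i:03d}", random_sequence(m, length, rng).residues))
        return out

    negative = draw_background(bg_ss, "neg")
    if paired:
        pos_base = [Sequence(f"pos_{i:03d}", s.residues) for i, s in enumerate(negative)]
    else:
        pos_base = draw_background(pos_bg_ss, "pos")

    positive: List[Sequence] = []
    rows = []
    for s, ss in zip(pos_base, implant_ss.spawn(n)):
        implanted, log = implant_motifs(s, spec, np.random.default_rng(ss))
        positive.append(implanted)
        rows.extend({"id": s.id, "position": p, "motif": m} for p, m in log)
    log_frame = pd.DataFrame(rows, columns=["id", "position", "motif"])
    return negative, positive, log_frame
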
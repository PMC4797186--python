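"""The PPV benchmark protocol and parameter-sweep runner.

A measure is scored on a negative/positive set pair as follows: compute
all unordered within-positive and within-negative pair similarities, pool
the two score lists, sort descending, and report the fraction of
positive pairs in the top half.  Equal set sizes make the two lists
equally long, so a PPV of 1 means perfect separation and 0.5 means no
discriminative power.  Ties straddling the cutoff are counted
fractionally — each tied positive contributes its expected inclusion
probability over uniform orderings of the tied block — which keeps the
protocol deterministic and makes ppv(pos, neg) + ppv(neg, pos) = 1 hold
exactly.

``run_experiment`` sweeps a (length x resolution x measure) grid over
replicated set constructions and reports the mean PPV with its standard
error per cell.  Replicate sets are shared across measures and
resolutions within a cell so that method comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence as TypingSequence

import numpy as np
import pandas as pd

from entroprof.background import BackgroundModel
from entroprof.measures import MEASURES, pairwise_matrix
from entroprof.sequence import Sequence, read_fasta
from entroprof.simulate import ImplantSpec, build_experiment_sets


@dataclass
class PPVResult:
    """Score lists of one experiment and the resulting PPV."""

    measure: str
    params: Dict[str, object]
    pos_scores: np.ndarray
    neg_scores: np.ndarray
    ppv: float


def ppv(
    pos_scores: TypingSequence[float] | np.ndarray,
    neg_scores: TypingSequence[float] | np.ndarray,
) -> float:
    """Fraction of positive pairs in the top half of the pooled ranking."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("score lists must be non-empty")
    if pos.size != neg.size:
        raise ValueError(
            f"score lists must have equal length, got {pos.size} and {neg.size}"
        )
    m = pos.size
    pooled = np.concatenate([pos, neg])
    cutoff = np.partition(pooled, pooled.size - m)[pooled.size - m]
    above = int((pooled > cutoff).sum())
    tied = int((pooled == cutoff).sum())
    slots = m - above  # tied scores compete for these remaining slots
    pos_above = int((pos > cutoff).sum())
    pos_tied = int((pos == cutoff).sum())
    return (pos_above + pos_tied * slots / tied) / m


def score_sets(
    negative: TypingSequence[Sequence],
    positive: TypingSequence[Sequence],
    measure: str,
    **params: object,
) -> PPVResult:
    """Score all within-set pairs of both sets and compute the PPV."""
    neg_scores = pairwise_matrix(negative, measure, **params).pair_scores()
    pos_scores = pairwise_matrix(positive, measure, **params).pair_scores()
    return PPVResult(
        measure, dict(params), pos_scores, neg_scores, ppv(pos_scores, neg_scores)
    )


_REQUIRED = ("n", "replicates", "seed", "background", "implant", "measures")


def _background_model(cfg: Dict[str, object]) -> Optional[BackgroundModel]:
    order = int(cfg.get("order", 0))
    base = np.asarray(cfg.get("base_probs", [0.25, 0.25, 0.25, 0.25]), dtype=float)
    if "transitions" in cfg:
        trans = np.asarray(cfg["transitions"], dtype=float)
    else:
        trans = np.tile(base, (4, 1))
    return BackgroundModel(order, base, trans, pseudocount=0.0)


def run_experiment(config: Dict[str, object]) -> pd.DataFrame:
    """Run the PPV sweep described by a configuration mapping.

    Required keys: n, replicates, seed, background, implant, measures.
    ``background`` is either ``{type: model, order, base_probs[,
    transitions]}`` or ``{type: fasta, path}``.  ``implant`` holds motifs,
    insertion_prob and mode.  The grid is the product of ``lengths`` (or
    a single ``length``), ``resolutions`` (word lengths) and ``measures``;
    sigma, order, revcomp, variance, include_nonoverlap and pseudocount
    apply to every cell where they are meaningful.

    Returns one row per grid cell with the replicate-mean PPV and its
    standard error.
    """
    for key in _REQUIRED:
        if key not in config:
            raise ValueError(f"missing required config field: {key!r}")
    if "lengths" in config:
        lengths = [int(v) for v in config["lengths"]]
    elif "length" in config:
        lengths = [int(config["length"])]
    else:
        raise ValueError("missing required config field: 'length' (or 'lengths')")
    resolutions = [int(v) for v in config.get("resolutions", [4])]
    measures = list(config["measures"])
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r} in config; valid: {MEASURES}")
    n = int(config["n"])
    replicates = int(config["replicates"])
    if n < 2 or replicates < 1:
        raise ValueError("config requires n >= 2 and replicates >= 1")
    if any(r < 1 for r in resolutions) or any(l < 1 for l in lengths):
        raise ValueError("resolutions and lengths must be positive")
    if max(resolutions) > min(lengths):
        raise ValueError(
            f"resolution {max(resolutions)} exceeds shortest length {min(lengths)}"
        )
    seed = int(config["seed"])
    sigma = float(config.get("sigma", 0.7))
    order = int(config.get("order", 1))
    revcomp = bool(config.get("revcomp", False))
    variance = str(config.get("variance", "exact"))
    include_nonoverlap = bool(config.get("include_nonoverlap", False))
    pseudocount = float(config.get("pseudocount", 1.0))
    paired = bool(config.get("paired", True))

    bg_cfg = dict(config["background"])
    bg_type = bg_cfg.get("type", "model")
    model = pool = gc_range = None
    if bg_type == "model":
        model = _background_model(bg_cfg)
    elif bg_type == "fasta":
        if "path" not in bg_cfg:
            raise ValueError("missing required config field: background.path")
        pool = read_fasta(bg_cfg["path"])
    elif bg_type == "heterogeneous":
        gc_range = tuple(bg_cfg.get("gc_range", (0.3, 0.7)))
    else:
        raise ValueError(
            "background.type must be 'model', 'fasta' or 'heterogeneous', "
            f"got {bg_type!r}"
        )

    imp_cfg = dict(config["implant"])
    for key in ("motifs", "insertion_prob"):
        if key not in imp_cfg:
            raise ValueError(f"missing required config field: implant.{key!r}")
    spec = ImplantSpec(
        tuple(imp_cfg["motifs"]),
        float(imp_cfg["insertion_prob"]),
        imp_cfg.get("mode", "revised"),
    )

    cell_seeds = np.random.SeedSequence(seed).spawn(len(lengths))
    rows = []
    for length, length_ss in zip(lengths, cell_seeds):
        rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in length_ss.spawn(replicates)]
        sets = [
            build_experiment_sets(
                n, length, spec, s, model=model, pool=pool,
                gc_range=gc_range, paired=paired,
            )
            for s in rep_seeds
        ]
        for res in resolutions:
            for measure in measures:
                params: Dict[str, object] = {"k": res, "order": order,
                                             "pseudocount": pseudocount}
                if measure in ("ep2", "ep2star"):
                    params.update(sigma=sigma, revcomp=revcomp)
                if measure == "ep2star":
                    params.update(
                        include_nonoverlap=include_nonoverlap, variance=variance
                    )
                values = [
                    score_sets(neg, pos, measure, **params).ppv
                    for neg, pos, _ in sets
                ]
                values = np.asarray(values)
                rows.append(
                    {
                        "measure": measure,
                        "length": length,
                        "resolution": res,
                        "sigma": sigma if measure in ("ep2", "ep2star") else np.nan,
                        "order": order,
                        "revcomp": revcomp,
                        "variance": variance if measure == "ep2star" else "",
                        "insertion_prob": spec.insertion_prob,
                        "replicates": replicates,
                        "mean_ppv": float(values.mean()),
                        "se_ppv": float(values.std(ddof=1) / np.sqrt(replicates))
                        if replicates > 1
                        else 0.0,
                    }
                )
    return pd.DataFrame(rows)
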
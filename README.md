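# entroprof

Multi-resolution alignment-free comparison of regulatory DNA sequences.

## The problem

Enhancers and other cis-regulatory modules (CRMs) are short stretches of
DNA (100–1000 bp) whose function is carried by clusters of transcription
factor binding sites — motifs of 6–15 bp that tolerate mismatches and act
independently of position, orientation and strand.  Two enhancers driving
the same expression pattern typically share binding-site *content* but
not sequence order, so alignment is the wrong tool; alignment-free
statistics compare sequences through their word-count vectors instead.
Classical statistics, however, fix one word length k in advance, and
their power collapses when k does not match the (unknown, heterogeneous)
motif lengths.  `entroprof` implements multi-resolution statistics that
aggregate words of every length up to L and standardise them with exact
count moments under a Markov background, together with the classical
fixed-resolution baselines, a motif-implantation simulator and the PPV
benchmark protocol used to compare such measures.

## The statistics

For a word w of length L with suffixes s_{w,k} (k = 1..L), the **simple
entropy** of w in a sequence is a kernel-weighted average of suffix
counts c_{w,k}:

    SE_w = Σ_k a_k c_{w,k} / Σ_k a_k,    a_k = exp(−(L−k)² / 2σ²).

SE_w is the multi-resolution analogue of a k-mer count: σ → 0 recovers
the plain L-mer count, larger σ lets shorter words contribute.  For two
sequences A and B the package computes

    D2   = Σ_w A_w B_w                         (raw counts, length k)
    D2s  = Σ_w ÃB̃ / √(Ã² + B̃²)
    D2*  = Σ_w ÃB̃ / ((n−k+1) p_w)
    EP2  = Σ_w A_SE_w B_SE_w
    EP2* = Σ_w (A_SE_w − E[A_SE_w])(B_SE_w − E[B_SE_w]) / √(Var_A[SE_w] Var_B[SE_w])

where Ã_w = A_w − (n−k+1)p_w and expectations/variances are taken under
an order-0 or order-1 stationary Markov model estimated from each
sequence.  Because occurrences of overlapping words of *different
lengths* are strongly dependent, Var[SE_w] requires the exact covariance
of variable-length word counts; `entroprof.moments` derives it in closed
form (self-overlap, partial-overlap, nested-suffix and disjoint terms)
and the test suite verifies it to 1e−10 against exhaustive enumeration
over all 4^l sequences.  An optional reverse-complement mode collapses
words into strand classes {w, rc(w)} and scores each class by the
maximum entropy of its two members.

## Worked example

Build a benchmark in which ten 4-kb background sequences with
heterogeneous GC content (negative set) are copied and implanted with the
variable-length motif family AGCCA, GCCA, TAGCCA, CCAG, AGCCAG at
insertion probability 0.008 per position (positive set), then ask each
measure to separate within-positive from within-negative pairs:

```python
from entroprof import ImplantSpec, build_experiment_sets
from entroprof.evaluate import score_sets

motifs = ("AGCCA", "GCCA", "TAGCCA", "CCAG", "AGCCAG")
spec = ImplantSpec(motifs, insertion_prob=0.008)
negative, positive, log = build_experiment_sets(
    10, 4000, spec, seed=1, gc_range=(0.3, 0.7)
)
print(f"implants per positive sequence: {len(log) / 10:.1f}")
for measure, params in [
    ("d2", {"k": 5}),
    ("d2star", {"k": 5}),
    ("ep2star", {"k": 5, "sigma": 0.6, "revcomp": True}),
]:
    res = score_sets(negative, positive, measure, **params)
    print(f"{measure:8s} PPV = {res.ppv:.3f}")
```

Output:

```
implants per positive sequence: 31.0
d2       PPV = 0.556
d2star   PPV = 0.911
ep2star  PPV = 0.911
```

Each positive sequence carries ~31 implanted motifs (~160 bp of signal
in 4000 bp).  Raw counts (D2) are dominated by the between-sequence GC
variation of the background and sit near the chance level 0.5;
the standardised statistics remove the compositional signal and rank
almost every positive pair above the negative ones (PPV 0.91; 1.0 is
perfect separation).  The multi-resolution EP2* keeps this power when
the resolution is mis-specified relative to the motif lengths, which is
the realistic regime — see `docs/methods.md`.

The same analyses are available from the shell:

```
entroprof simulate -n 10 -l 4000 -p 0.008 --motif AGCCA --motif GCCA \
    --motif TAGCCA --motif CCAG --motif AGCCAG --seed 1 --outdir bench/
entroprof score bench/positive.fa -m ep2star -k 5 --sigma 0.6 -o scores.tsv
entroprof profile bench/positive.fa -L 4 --phi 1.0 -o profile.tsv
entroprof evaluate config.yaml -o results.tsv
```

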
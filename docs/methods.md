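# Methods

## Model and procedure

A DNA sequence S = (X_1, …, X_l) is modelled as a stationary Markov chain
over {A, C, G, T} of order 0 (Bernoulli, "M0") or 1 ("M1").  The
probability that a word w occurs at a fixed position is
μ(w) = μ(w_1) ∏_j π(w_{j−1}, w_j); for order 0 the transition matrix is
defined as π(a, b) = μ(b) so both orders share one evaluation path.
Models are estimated per sequence by add-pseudocount frequencies (default
pseudocount 1.0), so every μ(w) is strictly positive and the standardised
statistics never divide by zero.  The initial distribution is the
smoothed empirical letter frequency, not the stationary vector of the
estimated π: the two differ by O(1/l) for realistic sequences, and no
stationarity is asserted for estimated models.  Where the closed-form
moments are checked exactly (see below), the test models are constructed
with their true stationary vector, because the formulas assume
stationarity and would not otherwise hold exactly.

The simple entropy SE_w of a word w of length L is the kernel-weighted
average of its suffix counts; pairwise measures are inner products of
per-sequence SE vectors over the full universe of 4^L words, optionally
centred and standardised by the exact per-word moments.  The word
universe is all 4^L words rather than the observed ones: a centred term
(0 − E[SE_w]) (0 − E[SE_w]) is non-zero even when a word is absent from
both sequences, and truncating to observed words would bias the sum.  A
hard limit L ≤ 12 keeps the dense count tables and the 4^L moment arrays
within ordinary memory; in practice L ≤ 7 is the regime of interest.

## Exact moments of variable-length word counts

E[c_{w,k}] = (l − k + 1) μ(s_{w,k}).  The variance of a single count sums
three contributions over ordered position pairs: the per-position
Bernoulli variance, partial self-overlap terms for shifts d = 1..k−1
(present only when the word's length-(k−d) suffix equals its prefix), and
disjoint-occurrence terms coupling positions more than k apart through
the chain memory, π^t.  The covariance of a word with one of its proper
suffixes classifies every position pair by the shift d of the shorter
word: inside the longer word (including the start-aligned case d = 0),
straddling its right end, hanging off its left end, or disjoint on either
side.  Every coefficient is the exact number of admissible position
pairs — a word of length k starts only at positions 1..l−k+1, so the
pair count is min(l−k'+1, l−k''+1−d) for rightward shifts and l−k'+1−d
leftward.  Var[SE_w] = aᵀ C a / (Σ a_k)², with C the L×L suffix-count
covariance matrix.

The implementation carries two independent code paths: a scalar per-word
reference (`moments.word_moments`) and a vectorised batch over all 4^L
words (`moments.batch_entropy_moments`); the test suite asserts their
agreement and validates both against probability-weighted exhaustive
enumeration of all 4^l sequences (l ≤ 6, words up to length 3, all suffix
pairs, three background models) at 1e−10.

**Neglecting disjoint terms.**  By default the scoring path drops the
disjoint-occurrence terms (`include_nonoverlap=False`), treating
occurrences separated by arbitrary background as independent.  Under M0
this is exact (π^t(a,b) = μ(b) makes the terms vanish identically).
Under M1 both the dropped sum and the variance grow linearly in l, so the
relative error converges to a small constant (at the percent level for
the chains exercised in the tests) rather than vanishing; it is a
deliberate speed/accuracy trade-off, and the exact terms are one flag
away.  With the terms dropped an assembled variance can come out
marginally non-positive in corner cases; it is clipped to 1e−12 with a
logged warning.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| L (resolution) | 4 | maximum word length; 4 suits unknown motif lengths of 4–8 bp |
| σ (kernel width) | 0.7 | Gaussian resolution kernel width; 0.7 weights (k=L, L−1, L−2) ≈ (1, 0.36, 0.017), σ→0 is single-resolution, large σ is uniform |
| φ | 1.0 | geometric weight of the per-position profile |
| model order | 1 | order-1 absorbs dinucleotide composition (e.g. CpG suppression) that order 0 mistakes for signal |
| pseudocount | 1.0 | add-one smoothing of letter/dinucleotide counts |
| revcomp | on (CLI) | strand classes {w, rc(w)} scored by their maximum entropy — enhancers act on either strand |
| include_nonoverlap | off | keep the exact disjoint-occurrence moment terms |
| variance | "exact" | EP2* denominator √(Var_A · Var_B); "poisson" uses √(E_A · E_B) |

Open conventions fixed by this package (the defining formulas are
single-sequence and leave the two-sequence case open): the D2* denominator
uses the geometric means of the two word probabilities and of the two
lengths; the EP2* denominator pools the two per-sequence variances as
√(Var_A·Var_B), mirroring how D2* pools the sequences, with the
"poisson" option provided because under it a thin kernel (σ = 0.01)
makes EP2* coincide with D2* to machine-level accuracy — the equivalence
the tests verify.  In reverse-complement mode each strand class takes the
maximum of the two member entropies per sequence, and the expectation and
variance attached to the class are those of the word attaining the
maximum (ties resolve to the lexicographically smaller member).  This
max rule is one defensible choice among several (mean, min, both-strand
sums); it favours the stronger signal.

## The per-position profile

`position_profile` computes the single-sequence entropic profile: at each
position i, a geometrically weighted sum of the counts of the suffixes
ending at i, standardised by the profile's own mean and (n−1)-normalised
standard deviation.  Positions i < L receive only the terms whose suffix
fits.  A constant profile (e.g. a homopolymer) has zero standard
deviation; its standardised values are defined as 0 and flagged.

## What the simulator emulates — and what it does not

`build_experiment_sets` realises the implantation benchmark: the negative
set is background; the positive set implants motifs into copies of the
same background draws (paired, so separation is attributable to the
implanted signal), or into an independent draw (`paired=False`, the
correct null when the insertion probability is 0, since the paired
construction with no implants yields bit-identical sets and a degenerate
all-ties PPV of exactly 0.5).

Background options:

* **model** — one shared M0/M1 chain; compositionally homogeneous.
* **gc_range / synthetic_genome_pool** — each sequence i.i.d. with its own
  GC content drawn uniformly from a range (default 0.3–0.7,
  strand-symmetric within a sequence).  This emulates the one feature of
  real genomic background that decides the benchmark: windows cut from
  different genomic locations differ markedly in composition, and that
  between-window variation dominates raw word-count statistics.  On a
  homogeneous background, raw D2 detects implanted motifs easily and the
  benchmark says nothing about standardisation.
* **pool** — N-free windows cut uniformly from user-supplied FASTA
  records (real intergenic sequence, when available).

Implantation scans left to right; each eligible position (those where the
longest motif fits) independently triggers with the stated per-position
probability; a triggered implant overwrites with a uniformly chosen motif
and the scan jumps past it, so implants never overlap and length is
preserved.  Whether the original transfer scheme draws one motif per
sequence or per position is ambiguous in the literature; the per-position
reading used here is recorded in output metadata.  The generator does
*not* emulate binding-site degeneracy (PWM sampling), repeats, spacing
constraints between sites, or long-range correlation — so a passing
benchmark demonstrates sensitivity to shared exact word content under
compositional noise, not robustness to motif mutation.

All randomness flows from one master seed through `numpy.random.
SeedSequence` spawning; every generated set and every experiment table is
bit-reproducible from (config, seed).

## Evaluation protocol

PPV: pool the m within-positive and m within-negative pair scores, sort
descending, and report the fraction of positive pairs among the top m.
Within-set pairing keeps the two lists equal-length for equal-size sets.
Ties straddling the cutoff count fractionally (expected inclusion over
uniform tie orderings), which is deterministic and makes
ppv(pos, neg) + ppv(neg, pos) = 1 an identity.  `run_experiment` reports
per-cell means over replicates with standard errors.

## Problem sizes used by the shipped checks

The acceptance tests exercise: exhaustive enumeration at l = 3..6 for all
words up to length 3 under three models; Monte-Carlo variance with
5·10⁴ chains of length 50 at L = 4, σ ∈ {0.5, 1.5}; thin-kernel
equivalence on ten 1 kb pairs; and the implantation benchmark at
l = 4000, insertion probability 0.008, L = 5, σ = 0.6, n = 10 with 5
replicates.  The acceptance script runs the null calibration with 50
replicates of 10×500 bp per set.  These sizes make the whole suite run
in well under a minute while leaving the Monte-Carlo and replicate
standard errors far smaller than the tested tolerances.

## Known limitations

* Markov orders ≥ 2 are not implemented (the moment derivations extend,
  the code does not).
* Moments are provided for a word and its suffixes, not for two arbitrary
  words of equal length; EP2* needs only the nested case.
* The max rule for strand classes attaches the argmax word's moments to
  the class; the distribution of a maximum of two dependent entropies is
  not itself computed.
* Estimated backgrounds are not forced to be stationary; the closed-form
  moments are exact only for genuinely stationary chains and are used as
  a high-quality approximation otherwise.
* N residues are masked out of every window rather than modelled.
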
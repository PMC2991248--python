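# Methods

## The problem

The branch point (BP) is the intronic adenosine that attacks the 5' splice
site during the first catalytic step of splicing, forming the lariat.  In
mammals the BP motif is highly degenerate — only the branch adenosine and a
T two bases upstream (the "TNA" signature) are strongly constrained — and
only a few dozen BPs have been mapped experimentally, so neither
consensus-matching nor straightforward supervised training works well.
`bpscan` implements a prediction strategy built around three observations:

1. the BP normally lies inside the AG exclusion zone (AGEZ), the 3'-terminal
   intron region devoid of AG dinucleotides, so candidates should be searched
   there rather than in a fixed window;
2. the degenerate motif is best described probabilistically, with a
   position-dependent order-1 Markov model (MM1) capturing the weak
   dependencies between adjacent motif positions;
3. BP recognition depends on the downstream polypyrimidine tract (PPT), so
   PPT features must enter the score.

## Coordinate convention

All positions are anchored at the 3' splice site: the last intron
nucleotide is −1, the 3SS AG occupies −2,−1, and "a BP at −23" means the
branch adenosine is the 23rd nucleotide from the intron end.

## AGEZ delimitation

Scanning 5'-ward from the 3SS, AG dinucleotides whose A lies within the
last `grace` nucleotides (default 12) compete with the actual acceptor
rather than delimit the zone and are ignored; the first AG beyond the grace
region is the AGEZ-defining AG, and the zone runs from it (exclusive of its
A) to −3.  With a defining A at −30 the zone is [−29, −3], length 27 =
|start| − 2.  When no defining AG exists within `max_extent` (default 500)
the zone truncates there.  Zones of rank k > 0 (the next AGEZ upstream) are
delimited by the same rule anchored at the previous defining AG's A:
AGs with their A within `grace` − 2 nucleotides of the anchor are skipped.
Whether the 3SS AG or the defining AG are counted in published per-intron
AGEZ lengths is not settled; the boundary convention here is explicit in
the `AGEZ` dataclass and configurable via `grace`.

Candidate BPs are 9-mers with T at position 4 and the branch A at position
6 (1-based), with the adenosine inside the search region and at least
`min_dist` = 15 nt upstream of the 3SS.  Windows containing N are skipped.

## Motif models

The MM1 factorizes the 9-mer probability along the chain of free positions
1→2→3→5→7→8→9; the invariant positions 4 (T) and 6 (A) are skipped, so
position 5 conditions on position 3 and position 7 on position 5 — a
second-order dependency across each fixed position.  The chain is an
argument (`chain=`) so alternative orderings can be compared; the default
is the only one used elsewhere in the package.  Initial and conditional
probabilities are estimated with a Laplace pseudocount (default 1,
configurable); both MM1 and the position-independent frequency model (PWM)
integrate to probability 1 over the 16,384 canonical 9-mers, which the test
suite checks exhaustively.

Scores are log-odds, log base 2, of a positive against a negative model.
The PWM log-odds is computed over the 7 free positions only, which makes it
the exact independence limit of the MM1 score.  Information content per
column is the standard 2 + Σ p log2 p bits; mutual information between
columns is the plug-in estimate, with pairs involving the two fixed
positions reported as NaN (blank).  The plug-in MI estimator has a positive
bias of roughly (|A|−1)²/(2 n ln 2) bits, which the tests account for.

## U2 duplex energy (optional)

Candidate/U2 duplex stability can be computed through a pluggable backend;
the shipped backend shells out to ViennaRNA's `RNAcofold`.  The candidate
9-mer (as RNA) is folded against the U2 branch-point-recognition oligo
`GUGUUAGUA` (the reverse complement of the consensus `UACUAACAC`) with the
hard constraint `|||||x|||&.........`: every candidate nucleotide is forced
to pair except the branch adenosine, which is forced unpaired (bulged), and
the U2 strand is unconstrained.  If no backend is available the feature
raises an explicit error; nothing falls back silently.

## Polypyrimidine tracts

A tract is a maximal subsequence satisfying: pyrimidine ends; no more than
two contiguous purines; every purine segment of length L surrounded by at
least 4L pyrimidines with both flanking pyrimidine segments ≥ L; T(GT)n
stretches allowed (a G flanked by T on both sides is treated as
pyrimidine-like for the purine rules, while still counting as G in
composition); and length ≥ 9 or at least 5 T.  Maximality means one-step
extension on either side violates some rule; overlaps among maximal tracts
are resolved greedily, longest first with ties to the 3'-most.  The
composition score is Σ w_n f_n with defaults w_T=3, w_C=2, w_G=−1, w_A=−2.
These weights are a documented stand-in preserving the intended qualitative
ordering (T-richness dominates; purine interruptions penalized); because
the SVM standardizes and re-weights features, downstream behaviour is
insensitive to affine rescalings of this score.

The "closest downstream PPT" of a candidate is the nearest tract whose 3'
end lies downstream of the branch adenosine; distance counts the
nucleotides strictly between the adenosine and the tract's 5' end and is
clamped at 0 when a maximal tract overlaps the adenosine (a tract that
absorbed flanking pyrimidines still supports the branch point).  When no
tract reaches downstream, a sentinel distance (500, the scan-window length)
and score 0 are returned.

## Classifier

Each candidate is described by four features: MM1 log-odds; pyrimidine
content between the branch A and the 3SS (positions (bp, −3], excluding
the 3SS AG, N excluded from the denominator); distance to the closest
downstream PPT; and that tract's score.  A support vector machine (linear
kernel by default, C = 1, RBF selectable) is trained on balanced classes —
the majority class is downsampled with a seeded RNG — after standardizing
features to zero mean and unit variance; the statistics are stored in the
model.  The kernel and C defaults are a design choice (4 interpretable,
low-dimensional features), not a validated match to any published
parameterization.  The decision function is re-implemented in numpy from
the extracted parameters so saved models are plain JSON and scoring is
exactly reproducible.

Per intron, candidates in the first AGEZ are ranked by SVM score, ties
going to the candidate closest to the 3SS.  Outcomes partition into four
categories: `no_candidates` (no canonical 9-mer in the last 500 nt),
`none_in_agez`, `negative_scoring` and `positive_scoring` (sign of the top
score at the zero threshold).  Predictions more than 100 nt from the 3SS
(about four times the average BP–3SS distance) are flagged distant (dBP).
A separate scanner scores all candidates in the last 500 nt (whole intron
if shorter) without the AGEZ restriction.

## Conservation-based training-set construction

Given per-intron alignments of the last 300 intronic nucleotides across 7
mammals (human first), a k-mer instance is *conserved* when its human
columns are consecutive in the alignment and identical, gap-free, in every
species.  Each of the 184 TNA-containing pentamers (patterns TNANN, NTNAN,
NNTNA) is classified from the positions of its conserved instances:

* test 1 — Kolmogorov–Smirnov against uniform over [−300, −1];
* test 2 — one-sided binomial test that the fraction of instances inside
  the window (−55, −15) exceeds the window's share (41/300) of the scanned
  region (no edge-effect correction; the convention is configurable);
* peak — mode of a 5-nt-binned histogram after a 3-bin moving average.

Failing either test at α = 0.001 ⇒ unassociated; passing both with the
peak inside the window ⇒ BP-associated, outside ⇒ PPT-associated.  The
window test uses the pentamer's start position; "peak" is not defined in
the source literature, so the binned-mode definition above is this
package's and is deterministic (ties break to the 5'-most bin).

The positive set is then built in two steps: introns with a *single*
conserved TNA trinucleotide, with its adenosine in (−55, −15), contribute
the human 9-mer centred on it; and an instance is kept only if, in every
species' own (ungapped) sequence, at least one BP-associated pentamer
overlaps the TNA (shares ≥ 1 position with the trinucleotide; an
alternative mode accepts any overlap with the 9-mer).  This tolerates
sequence variation while requiring functional conservation.

## Baselines and benchmarking

Consensus baselines rank 9-mers with an A at position 6 by Hamming
distance to TACTAACAC inside a fixed window (100 or 200 nt), optionally
preferring the 3'-most among equal-distance hits; candidates beyond a
maximum distance (default 2 — the original cutoffs are not recoverable)
are discarded.  The PWM baseline ranks AGEZ candidates by PWM log-odds.
An intron with several mapped BPs counts as a hit if any is recovered;
sensitivity is TP over introns, PPV is TP over introns with a prediction,
and standard errors are binomial, sqrt(p(1−p)/n).  EST inclusion of an
exon is 100·I/(I+S); a separate coverage filter (default I+S ≥ 10) flags
exons with too few ESTs.

## Synthetic data: what it emulates and what it does not

The generator plants, in each intron: a canonical 9-mer sampled from a
configurable motif model at a position drawn from a rounded normal
(centre −24, sd 5) truncated to [−55, −15]; a pure-C/T, T-rich tract
(length 10–20, T fraction 0.7) a few nucleotides downstream, kept long
enough (or T-rich enough) to satisfy the tract rules even when squeezed
against the 3SS; and an AG exclusion zone ending 5–20 nt upstream of the
9-mer at a planted defining AG, with internal AGs beyond the grace region
scrubbed to pyrimidines.  Background composition is A/C/G/T =
0.27/0.21/0.21/0.31; intron lengths are lognormal (median ≈ 700 nt,
clipped to [300, 1500]).  Planted 9-mers containing an AG are resampled so
the planted BP remains inside its own AGEZ.

The default planted motif is an MM1 whose marginals follow a degenerate
YTNAY-style consensus and whose transitions favour retaining the
purine/pyrimidine class of the preceding position (boost factor 3), so
adjacent positions carry genuine first-order dependencies.  The signal
strength was set from a Bayes-detectability diagnostic: with the true
model and position prior, the Bayes-optimal top-1 recovery on the default
cohort is ≈ 0.90, so the pipeline's measured recovery (≈ 0.86) reflects
the method rather than an information-theoretic ceiling, and the ≥ 0.8
recovery property is meaningful.  This deliberately makes the synthetic
motif more informative than the human one (whose total information
content, 4.739 bits including the fixed positions, is far lower): passing
the recovery tests shows the pipeline finds planted signals at this
detectability, not that human BPs are this clean.  Other features of real
introns the generator does not emulate: GC-content strata, non-TNA BPs,
multiple BPs per intron, alignment errors and indel-rich orthology.

Alignment blocks derive 6 further species from the human last-300 nt by
independent per-site substitution (identity 0.9) and optional deletion;
the planted 9-mer is copied intact per species with probability 0.95.  In
the pentamer-recovery experiment the "planted family" is the set of
pentamers planted at least 20 times (below that the positional tests lack
power by construction) and "background" pentamers are those never planted;
pentamers planted a handful of times are neither and are excluded from the
metric.

## Problem sizes and numerics

The packaged experiments use 5,000 introns (training on all planted
positives with an equal number of sampled TNA negatives, 10-fold
cross-validation on the same entries with per-fold refitting of the motif
models so test 9-mers never inform the scoring) and 2,000 alignment
blocks.  All randomness flows from explicit integer seeds through numpy
Generators; retraining with the same seed reproduces identical decision
values.  Zero-count transition rows under a zero pseudocount are set
uniform (they are unreachable from the data); log-odds under pseudocounted
models are finite by construction.  Standardization guards against
zero-variance features by leaving them unscaled.

## Known limitations

* The PPT score weights and the consensus-baseline distance cutoffs are
  documented stand-ins, not transcriptions of the original values.
* The SVM kernel/C are not validated against the original tool; benchmark
  ranks may be sensitive to this choice.
* Real-data reproduction (information content, cross-validation numbers on
  conservation-derived training sets) requires user-supplied genome
  sequences and alignments; the `ic` and `train` commands provide the
  workflow but the package ships no genome data.
* Non-TNA branch points (and U12-type introns) are out of scope and would
  require independent modelling.
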
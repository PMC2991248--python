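# bpscan

Branch-point prediction in mammalian introns.

The branch point (BP) is the intronic adenosine that attacks the 5' splice
site in the first step of pre-mRNA splicing, forming the lariat.  In
mammals the BP motif is extremely degenerate — essentially only the branch
A and a T two bases upstream (TNA) are constrained — which defeats simple
consensus matching.  `bpscan` predicts BPs by combining:

* **AGEZ-restricted search** — candidates (canonical 9-mers `NNNTNANNN`
  with T at position 4 and the branch A at position 6) are enumerated
  inside the AG exclusion zone, the 3'-terminal region of the intron devoid
  of AG dinucleotides, rather than in a fixed window;
* **a position-dependent order-1 Markov model (MM1)** of the 9-mer signal
  over the free-position chain 1→2→3→5→7→8→9, scored as a log₂-odds
  S = log₂ P(x | positive) − log₂ P(x | negative);
* **polypyrimidine-tract (PPT) features** — a rule-based finder for maximal
  pyrimidine tracts, scored Σₙ wₙ fₙ, feeding the candidate's pyrimidine
  content to the 3SS and the distance/score of its closest downstream
  tract;
* **a support vector machine** over the four features (MM1 score,
  pyrimidine content, PPT distance, PPT score), trained on balanced
  positive/negative sets; the signed decision value ranks candidates and
  its sign at the zero threshold labels them.

The package also implements the conservation pipeline used to build a
positive training set without mapped BPs (positionally biased conserved
TNA pentamers across 7 mammals, and the unique-conserved-TNA instance
selection), consensus- and PWM-based baseline predictors with benchmark
metrics, and a fully seeded synthetic-intron generator with planted truth
so the entire pipeline is testable without genome downloads.

Intended users: computational biologists studying 3' splice-site
architecture, alternative splicing, or splicing-disrupting variants.

## Worked example

Generate 200 synthetic introns with known (planted) branch points, train a
model on the planted truth, and predict:

```sh
bpscan simulate -o demo --n 200 --seed 11
bpscan train --fasta demo.fasta --truth demo.truth.tsv -o demo_model --seed 11
bpscan predict --model demo_model demo.fasta | head -4
```

```
intron_id  agez_len  bp_pos  ninemer    mm1_score  py_content  ppt_dist  ppt_score  svm_score  rank  category          distant_flag
syn00000   25        -17     GACTTACCT  0.7420     0.8571      0         37         2.0112     1     positive_scoring  0
syn00001   46        -28     GTTTAATTT  3.5583     0.8400      0         80         3.0710     1     positive_scoring  0
syn00002   49        -29     GCCTTACTT  0.5736     0.7308      0         50         0.6208     1     positive_scoring  0
```

Per intron you get the AGEZ length, the top-ranked candidate's branch-A
position (3SS-anchored: −17 means the 17th nucleotide from the intron
end), its 9-mer, the four features, the SVM score, and the outcome
category (`positive_scoring` / `negative_scoring` / `none_in_agez` /
`no_candidates`).  Here all three top predictions recover the planted
positions (compare `demo.truth.tsv`: syn00000 planted at −17 with 9-mer
GACTTACCT).  `bpscan agez` tabulates the zones themselves:

```
intron_id  agez_length  defining_ag_pos  n_candidates
syn00000   25           -28              1
syn00001   46           -49              2
```

Other subcommands: `ppt` (tract tables), `scan` (last-500-nt scan without
the AGEZ restriction), `benchmark` (SVM vs consensus/PWM baselines against
a truth table), `pentamers` (the 184-member TNA pentamer space), and `ic`
(information content of a user-supplied 9-mer set — the entry point for
reproducing signal statistics on real conservation-derived training data,
which requires genome sequences the package does not ship).

The library mirrors the CLI: `bpscan.find_agez`, `enumerate_candidates`,
`fit_mm1`, `mm1_score`, `find_ppts`, `predict_intron`, the
`bpscan.trainset` conservation pipeline and the `bpscan.synthetic`
generator.  See `docs/methods.md` for the model details, parameter
defaults and design choices.

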
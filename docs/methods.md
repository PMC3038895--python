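# Methods

## Model

A taxon is modelled by its relative abundance index (RAI) profile: for
every k-mer w = x₁…xₖ and every Markov order i ∈ {0, …, k−2},

    rai_i(w) = log2 [ p(w) p(sfx_i) / ( p(sfx_{i+1}) p(x_1..x_{k-1}) ) ]

where sfx_i is the length-i suffix ending at position k−1 (the empty
word, with probability 1, for i = 0) and sfx_{i+1} the length-(i+1)
suffix ending at position k. Each term is a log-odds between the
observed probability of w and its expectation if the final base
depended only on the preceding i bases; the profile score is the
superposition Σᵢ rai_i(w). The per-order terms telescope to

    (k−1)·log2[p(w)/p(x_1..x_{k-1})] + Σ_{i=0}^{k-2} log2[p(sfx_i)/p(sfx_{i+1})],

an identity the test suite checks against independent term-by-term
evaluation. When counts are uniform at every length, every term is
exactly zero in floating point (all probabilities are exact powers of
1/4): the all-zero profile is the "observed = expected" fixed point.

A fragment F with valid-window k-mer relative frequencies f_F is scored
against profile G by E_F[rai^G] = Σ_w f_F(w) rai^G(w), assigned by
argmax over profiles, and given the margin q(F) = best − second-best as
a quality score. Normalising f_F by the fragment's valid window count
(rather than using raw counts) leaves the argmax unchanged — proven as a
test property — but makes E_F comparable across fragment lengths, which
the refinement loop's mean-score trajectory relies on.

### Assumptions

- Probabilities of all orders 1..k come from one collection of
  sequences, counted on the given strand only (profiles are
  directional; an opt-in flag adds reverse-complement windows).
- Windows containing N are dropped independently at each length.
- The statistic cancels low-order composition by construction: two
  sources that differ mainly in base or dinucleotide frequencies while
  sharing higher-order conditional structure get similar profiles and
  can be confused. This is the price of exploiting long-range
  correlations; see Limitations.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| k | 7 | bases | accuracy saturates near k = 7 while 4^k stays tractable; 2–8 supported |
| pseudocount | 0.01 | counts/word | see Smoothing |
| update_min_bp | 25,000 | bp | minimum assigned sequence before a class's profile is retrained |
| stop_tol | 0.01 | relative | stop when the mean membership score changes < 1% |
| max_iters | 30 | iterations | hard termination cap; 3–6 suffice in practice |
| quality top-p | 100 (off) | % | per-class fraction kept classified, rest "unknown" |

## Smoothing

Unseen k-mers would give log(0), so probabilities are add-pseudocount
smoothed: P(w) = (c_w + ε)/(W_m + ε·4^m) at each length m. The choice
of ε matters more than it looks: the pseudo-mass fraction ε·4^m/W_m
grows by a factor 4 per length, so a large ε (e.g. the classic add-one)
shrinks the k-mer level toward uniform far more than the (k−1)-mer
level. That asymmetry biases the scores of common words downward, and
since a same-source fragment weights exactly those words, it can invert
classification outright (measured: 0/100 same-source wins at k = 7 with
ε = 1 on 500 kbp training genomes, 100/100 with ε = 0.01). The default
ε = 0.01 keeps every probability finite while leaving observed
frequencies essentially raw; ε is configurable, including 0 for exact
oracle arithmetic on saturated toy data.

## Refinement

Hard-EM over a fixed class set: (1) classify all fragments against the
current profiles; (2) for every class whose assigned fragments total
more than update_min_bp, replace its profile with one trained on those
fragments alone (a config option pools fragment counts with the seed
sequences instead); (3) stop when |mean_cur/mean_prev − 1| < stop_tol
or at max_iters. The mean is over classified fragments' best scores.
The update gate counts summed fragment lengths, overlap-unaware. When
every class is under the gate, iteration 2 reproduces iteration 1
exactly and the loop stops — the fixed point is tested. Classes never
die or split; unclassifiable fragments (shorter than k, or no N-free
window) are carried through flagged, never silently dropped.

## Evaluation

Per class i at a rank r: Sn_i = TP_i/(TP_i+FN_i+U_i) and
Sp_i = TP_i/(TP_i+FP_i), with U_i the unknown/unclassifiable count. A
hit is a TP at rank r iff the assigned profile's lineage matches the
truth lineage at r, so clade-exclusion experiments (the whole clade of
the test genome removed at some rank, scored one rank up) credit sister
taxa. Sp is reported as missing, not 0, for classes with no
predictions, and macro-averages skip missing values, keeping
"mean specificity" honest. Fragments whose rank is missing from both
lineages go to an `unresolvable` tally rather than any class.

## Synthetic data

The generator emulates one thing: pervasive, taxon-specific
oligonucleotide usage whose similarity decays with taxonomic distance.
A rank tree (default 2 phyla × 2 families × 2 genera × 1 species = 8
species) starts from a random order-3 Markov source; every edge
multiplies the parent's transition rows by exp(divergence · N(0,1)) and
renormalises (divergence 0.35/edge by default), and each leaf emits a
500 kbp genome. All randomness flows from one root seed through numpy
SeedSequence state.

Source order 3 is deliberate. Perturbing a low-order chain (order ≤ 2)
puts most of the sibling divergence into stationary base composition —
exactly the component the RAI statistic cancels — which makes such
fixtures fragile in a way real genomes are not: genuine genome
signatures differ in higher-order structure (codon usage, di/tri-nucleotide
context effects). An order-3 chain gives the statistic the kind of
signal it was built to exploit while staying cheap to simulate.

What the generator does **not** emulate: genes and codon periodicity,
GC skew and replication strand asymmetry, repeats, horizontal transfer,
read errors, chimeras, coverage bias, inter-genome length variation.
Passing tests therefore demonstrate that the statistical machinery is
correct and that the method behaves as designed when its premise (a
higher-order compositional signature) holds — not that real communities
reach these accuracies.

## Numerical and design choices

- Deterministic tie-breaks everywhere: profile ties go to the
  lexicographically smallest ref_id; quality-threshold ties within a
  class order by (quality desc, frag_id asc).
- Single-profile databases: the runner-up is undefined and q(F) = +inf
  (the fragment trivially fits the only model best).
- Quality thresholding keeps ceil(p/100 · n) fragments per assigned
  class and is applied only after refinement converges.
- Profile databases serialise scores as shortest round-tripping decimal
  text (`repr`), making write → read → write byte-identical without
  binary formats.
- Replicon concatenation is plain (no separator); the few chimeric
  junction k-mers are accepted. Internal coordinates are 0-based
  half-open.
- Problem sizes in the test-suite and acceptance runs (500 kbp genomes,
  1000 × 400 bp fragments per species, 200-fragment dominance checks)
  are chosen to estimate each statistic stably at minute scale.

## Limitations

- Discrimination degrades for taxa whose divergence is mostly
  low-order compositional (see Assumptions); a Euclidean-distance
  tetranucleotide method can beat the RAI statistic in that regime.
- Profiles trained on barely more than the 25 kbp gate are noisy at
  4^7 = 16,384 dimensions; the gate prevents the worst of it but small
  classes still refine on thin data.
- The class set is fixed to the seed database: organisms with no seeded
  relative are forced into the nearest available bin rather than
  discovered de novo.
- Directional counting means profiles of the same genome sequenced on
  opposite strands differ; use the reverse-complement option for
  strand-agnostic work.
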
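# raibin

Composition-based taxonomic binning of metagenomic DNA fragments using
relative abundance index (RAI) profiles with iterative model refinement.

## The problem

Metagenome assemblies yield fragments from a few hundred bp to tens of
kbp whose source organisms are usually absent from reference databases.
Alignment-based binning fails when no close relative has been sequenced;
composition-based binning exploits the fact that short-oligonucleotide
usage is a pervasive, taxon-specific genome signature. `raibin`
implements a higher-order log-odds signature and a semi-supervised
(hard-EM) refinement loop that adapts reference models to the sample
itself, for anyone who needs to assign fragments, reads or contigs
(~100 bp – 50 kbp) to taxa at ranks from species to phylum.

## The statistic

For a k-mer *x*₁…*x*ₖ with probabilities estimated from a sequence
collection, the order-*i* relative abundance index is the log-odds of
the observed k-mer probability against its expectation under an order-*i*
Markov assumption:

    rai_i(x_1..x_k) = log2 [ p(x_1..x_k) p(x_{k-i}..x_{k-1})
                             / ( p(x_{k-i}..x_k) p(x_1..x_{k-1}) ) ]

with the length-0 suffix read as the empty word (probability 1), so
rai₀ tests plain base independence. The profile score of each k-mer is
the superposition `rai = Σ_{i=0}^{k-2} rai_i`; the 4ᵏ-vector of scores
(default k = 7) is the taxon's RAI profile — positive where a k-mer is
over-represented relative to Markov expectation, negative where it is
under-represented, identically zero when observed counts are uniform.

A fragment *F* is scored against profile *G* by the frequency-weighted
sum `E_F[rai^G] = Σ_w f_F(w) rai^G(w)` over its k-mer relative
frequencies, assigned to the argmax profile, and given a quality score
`q(F) = E_F[best] − E_F[second]` used for top-p% thresholding.
Refinement repeats classify → retrain (each class's profile is rebuilt
from the fragments assigned to it, when they exceed 25 kbp) until the
mean membership score changes by less than 1%.

## Worked example

`examples/02_iterative_refinement.py` simulates the standard 8-species
mixture (order-3 Markov genomes of 500 kbp), seeds the database with
profiles of *perturbed relatives* — the realistic case where the sampled
species themselves are unsequenced — and refines:

```
converged after 3 iterations (tolerance)
  iteration 1: mean membership score 1.3488
  iteration 2: mean membership score 1.7831
  iteration 3: mean membership score 1.7883

species-level accuracy before refinement: 91.69%
species-level accuracy after refinement:  92.46%
```

The mean membership score rises as retrained profiles fit the fragment
clusters and saturates; the 1% stopping rule then fires. See
`examples/01_profiles_and_classification.py` (profiles, E_F, quality
scores) and `examples/03_clade_exclusion_evaluation.py` (clade-exclusion
evaluation and the sensitivity/specificity trade-off).

## Command line

```
raibin simulate refs.fa tax.tsv            # synthetic reference fixture
raibin build-db refs.fa tax.tsv db.raidb   # train the profile database
raibin bin frags.fa db.raidb out.tsv       # classify + refine
raibin eval out.tsv truth.tsv db.raidb eval.tsv --rank genus
```

All defaults follow the standard operating point (k = 7, 25 kbp update
gate, 1% stopping rule); outputs are TSV with a `#` config header.

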
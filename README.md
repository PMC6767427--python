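# codivergence

Full-likelihood Bayesian tests for **shared divergence times** among pairs
of populations, from biallelic characters (e.g. RADseq loci).

## The problem

Climate-driven "species-pump" models predict that population pairs
co-distributed across the same historical barrier — for example, islands
repeatedly joined and re-fragmented by Pleistocene sea-level cycles —
should have divergence times clustered around the fragmentation events.
Testing this is a model-choice problem: given sequence data from *n*
population pairs, how many distinct divergence events best explain the
data, and which pairs share an event?

Each comparison is modeled as a two-tipped species tree: two populations
with constant mutation-scaled effective sizes θ₁ and θ₂ = *N*ₑμ diverge at
time τ (in expected substitutions per site; the mutation rate is fixed at
1) from an ancestral population whose size is a multiplier times the mean
of the descendant sizes, with no migration afterwards.  The likelihood of
each biallelic site is computed by analytically integrating over all gene
trees and mutational histories under the symmetric two-state substitution
model, so no gene trees are ever sampled.  A Dirichlet process with
concentration α (itself given a gamma hyperprior) is the prior over the
assignment of comparisons to divergence events; for *n* = 8 pairs there
are B(8) = 4140 possible divergence models.  MCMC samples the joint
posterior over the partition, the event times, the demographic parameters,
and α.  Support for *k* divergence events is summarized with Bayes factors

BF(k) = [P(k | data) / (1 − P(k | data))] / [P(k) / (1 − P(k))],

and codivergence of a specific pair of comparisons is judged against the
pairwise prior probability E[1/(1+α)] — or, for pairs singled out *a
posteriori*, against the corrected prior 1 − P(all independent).

The package provides:

* `data_io` — per-locus FASTA / NEXUS reading, population maps, biallelic
  recoding (polyallelic sites removed or recoded), weighted site-pattern
  compression, dataset summaries;
* `likelihood` — the exact two-population pattern likelihood plus an
  independent Monte-Carlo gene-tree oracle (msprime + pruning);
* `dpp` — Bell numbers, CRP partition probabilities, Stirling-number
  distributions of the number of events, gamma-hyperprior marginals;
* `mcmc` — auxiliary-variable Gibbs scans over partitions,
  Metropolis-Hastings updates with prior-independence components, the
  Escobar–West α update, PSRF and ESS diagnostics;
* `simulate` — template-matched coalescent simulation that reproduces an
  empirical sampling skeleton exactly (loci × sites × per-site gene-copy
  counts, i.e. the missing-data pattern), with an optional
  one-SNP-per-locus filter;
* `summarize` — P(k) tables, Bayes factors, codivergence matrices,
  divergence-time summaries, nucleotide diversity, the loci-splitting
  vetting workflow, and simulation performance reports;
* a `codivergence` CLI with `analyze`, `simulate`, `summarize`, `vet` and
  `priors` subcommands driven by one YAML config.

## Worked example

Prior structure and the headline Bayes factors for eight pairs
(`python analysis/01_prior_models.py`):

```
divergence models for 8 pairs: 4140
prior mean number of events at the Gamma(1.5, 3.13) mean (alpha = 4.695): 5.000

anchors: P(k=8 | Gamma(1.1,56.1)) = 0.496 (about half the prior mass on
independent divergences); P(k=1 | Gamma(0.5,1.31)) = 0.499

Bayes factors:
                         comparison       hyperprior  prior_prob  bayes_factor            direction
most-similar pair (posterior 0.385) Gamma(1.1, 56.1)       0.504         1.623 against codivergence
     split halves (posterior 0.963) Gamma(1.5, 3.13)       0.265        72.115     for codivergence
     split halves (posterior 0.889) Gamma(1.1, 56.1)       0.052       145.887     for codivergence
```

Reading the table: under the default hyperprior, half the prior mass sits
on "all eight pairs independent", so a pair singled out *after* seeing the
posterior needs posterior probability above ~0.5 to earn support — at
posterior 0.385 the Bayes factor is a weak 1.6 *against* codivergence.
Conversely, when one comparison's loci are split at random into two
pseudo-comparisons (which codiverged by construction), posterior
probabilities of 0.963 and 0.889 translate into Bayes factors of ~72 and
~146 for codivergence.

A vetting run on simulated data
(`python analysis/03_vet_by_splitting.py`):

```
simulated pair: tau = 0.005583, 400 loci split into 200 + 200
posterior co-assignment probability 0.766 vs pairwise prior 0.265; Bayes factor 9.1 for codivergence
```

`python analysis/02_simulation_study.py` runs a scaled-down estimator
performance study (RMSE, credible-interval coverage, confusion of true vs
estimated event counts) for the all-sites and one-SNP-per-locus analyses;
see `docs/methods.md` for what its results do and do not show.

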
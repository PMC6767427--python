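# Methods

## Model

Each comparison is a pair of populations treated as a two-tipped species
tree.  Three branches carry constant mutation-scaled effective sizes: the
descendants θ₁, θ₂ and the ancestor θ_root = multiplier × (θ₁ + θ₂)/2.
The pair diverges at time τ, measured in expected substitutions per site
(the mutation rate is fixed at 1, making θ = *N*ₑμ and τ = *t*μ; absolute
times and sizes are not separately identifiable).  There is no migration
after divergence, no recombination within a locus, and free recombination
between loci.  Characters are biallelic and evolve by the symmetric
two-state analogue of Jukes–Cantor: each lineage flips allele at rate 1,
so the probability of no net change over time *t* is (1 + e^(−2t))/2 and
the stationary frequencies are (½, ½).  Because the process is symmetric,
inference is invariant to which allele is coded 0 — the property that
makes the "first nucleotide in the column is state 0" recoding harmless.

Comparisons are tied together only through the prior: a Dirichlet process
partitions the comparisons into divergence events sharing a τ.  The
concentration parameter α controls the prior tendency to share events and
carries a Gamma(shape, scale) hyperprior.  Named presets pin the three
analysis regimes: Gamma(1.1, 56.1) places about half the prior mass on all
eight comparisons diverging independently, Gamma(1.5, 3.13) implies a
prior mean of five events for eight comparisons, and Gamma(0.5, 1.31)
places about half the mass on a single shared event.  Base priors:
τ ~ Exponential(mean 0.005, 0.0005 or 0.05 by preset), θ ~ Gamma(shape 4,
mean 0.004), root multiplier ~ Gamma(shape 100, mean 1).

## Likelihood computation

The probability of a site pattern (n₁, r₁, n₂, r₂) — nᵢ sampled gene
copies, rᵢ of them carrying allele 1 — is computed without sampling gene
trees, using a *killed ancestral process* that is algebraically identical
to partial-likelihood pruning but works with probability mass over counts.
Backward in time the sampled lineages form a Markov chain on states
(m, j): each lineage flips allele at rate 1 (reversibility makes the
backward mutation process identical to the forward one), every same-allele
pair coalesces at rate 1/(2θ), and a coalescence between lineages carrying
different alleles would contradict the mutational history, so that event
kills the path.  Tip data give a point mass at (nᵢ, rᵢ); each descendant
branch evolves this mass for duration τ via the matrix exponential of the
(m, j) sub-generator (≤ (n+1)(n+2)/2 states, dense); at the divergence the
two populations' mass vectors convolve ((m₁, j₁) ⊗ (m₂, j₂) →
(m₁+m₂, j₁+j₂)); the infinite root branch contributes the exact absorption
probability into a single surviving lineage, obtained from a
level-by-level tridiagonal linear solve rather than any finite-time
truncation, and the final lineage is weighted by its stationary ½.  The
pattern probability includes the binomial multiplicity C(n₁,r₁)C(n₂,r₂) —
a data-dependent constant — so probabilities over all (r₁, r₂) sum to one
exactly; the likelihood is *not* conditioned on sites being variable.
Missing bases simply reduce the per-site nᵢ; a site empty in one
population enters through the other population's branch alone.

The coalescence-rate convention (a pair coalesces at rate 1/(2θ)) is
isolated in one constant.  τ and θ only enter jointly through this rate
and the flip rate, so any alternative scaling is a reparameterization.

Correctness is established three ways: exact agreement with the
two-lineage closed form P(same allele) = ½(1 + e^(−4τ)/(1 + 8θ_root));
normalization to 1e−8 over all sample configurations up to six copies; and
agreement, within Monte-Carlo error, with an independent oracle that
simulates gene trees under the same demography with msprime and averages
Felsenstein-pruning probabilities over trees.  The infinite-root solve is
additionally checked against long finite-time propagation (doubling the
branch until less than 1e−10 of the mass remains on multi-lineage states;
agreement within 1e−8).

## MCMC

One sweep updates, in order: (1) the partition, by a per-comparison Gibbs
scan with auxiliary events — each comparison chooses among existing events
(weight: occupancy × likelihood) and fresh events with times drawn from
the τ prior (weight: α/m_aux × likelihood), the vacated time serving as an
auxiliary when the comparison was a singleton; (2) each event time and
each comparison's (θ₁, θ₂, multiplier), by Metropolis–Hastings mixing a
multiplicative random walk (log-scale window, Jacobian-corrected) with
independence proposals from the prior — the independence component makes
prior-only runs draw nearly independent samples and helps tight posteriors
escape initialization; (3) α, by the Escobar–West beta-augmented
conditional draw given the current number of events (skipped when α is
fixed).  The random-walk scale adapts toward ~30 % acceptance during the
burn-in window only and is frozen afterwards, so retained samples come
from a fixed kernel.  Per-chain seeds derive deterministically from the
master seed; identical configurations reproduce traces bit-for-bit.

Sampler validation: with the likelihood disabled, 10⁴ thinned samples
reproduce every prior marginal (Kolmogorov–Smirnov / χ² at the 0.01
level); with data from one pair and demography pinned by near-point-mass
priors, the MCMC marginal of τ matches a brute-force normalized grid
posterior (sup-CDF distance < 0.05).

Chains record every sampled generation including the initial state, so a
chain of G generations sampled every s yields G/s + 1 samples; burn-in
(counting the initial state) is applied at summary time.  Diagnostics are
the multi-chain potential scale reduction factor (square root of the
Brooks–Gelman corrected statistic) and an effective sample size from the
autocorrelation sum with Geyer-style initial-monotone truncation of paired
lags — the cited estimator families admit variants, so these exact choices
are pinned here and tested against closed forms (iid: ESS ≈ n; AR(1) with
coefficient φ: ESS/n → (1−φ)/(1+φ)).  Default reporting thresholds mirror
the analysis regime they summarize: ESS > 2000, PSRF < 1.005, with 1.2 as
the highlight threshold in simulation reports.

## Template-matched simulation

A simulation template is the exact sampling skeleton of a dataset: loci
per comparison, sites per locus, and gene copies sampled per population at
every site (the empirical missing-data pattern).  A replicate draws α from
its hyperprior, the partition from the CRP, event times from the τ prior
and demographic parameters from theirs, then simulates one structured-
coalescent gene tree per locus (msprime, two demes merging at τ, pair
coalescence rate 1/(2θ)) for the union of copies observed anywhere in the
locus, evolves every site independently along that tree under the rate-1
flip process with a stationary root state, and masks per-site absent
copies.  Which copies are masked is arbitrary under exchangeability; the
trailing copies are masked for determinism.  The one-SNP-per-locus filter
keeps the first variable site in locus order (the deterministic resolution
of "at most one variable site per locus").  Truth is recorded before any
analysis; replicate seeds are derived as hash(master seed, replicate
index).

What the simulator emulates: the linkage of all sites in a locus on one
gene tree, prior-distributed truth, and arbitrary missing-data skeletons.
What it does not emulate: data-acquisition bias (no ascertainment of
variable loci), sequencing error, intralocus recombination, and migration.
Passing tests therefore certify the inference machinery under the model's
own assumptions plus within-locus linkage — not robustness to assembly
artifacts of real reduced-representation data.

## Desk-scale study sizes and what they show

The performance study uses 100 replicates of 4 comparisons with 500 loci ×
100 sites and 4 gene copies per population (two diploid individuals, the
low end of the empirical sampling), truth drawn from the α ~ Gamma(1.5,
3.13), τ ~ Exponential(0.005) simulation priors, analyzed with single
adaptive chains of 800 sweeps (150 discarded); pilot runs showed chains
ten times longer change neither point estimates nor interval coverage.
Two behaviors separate cleanly at this scale:

* **Point estimation is accurate and calibrated under the model.**  With
  unlinked sites (one site per locus) 95 % credible-interval coverage is
  nominal, and posterior means track truth tightly in both designs.
* **Linked sites buy precision at the cost of interval calibration.**
  With 100 linked sites per locus the likelihood treats 50,000 sites as
  independent draws while only ~500 independent gene trees exist, so
  posterior variances are understated and interval coverage falls well
  below nominal; the same overconfidence occasionally splits one true
  event into two.  Linkage leaves expected site patterns unchanged — it
  only reduces their effective variance — which is why point estimates
  stay accurate while intervals narrow.  The acceptance suite asserts
  nominal coverage under the linked design and is expected to flag this;
  the test measures the effect rather than hiding it.
* **Variable-only data need a conditioned likelihood the package does not
  provide.**  The likelihood is never conditioned on sites being variable
  (a deliberate non-goal).  Feeding it one-SNP-per-locus data therefore
  inflates divergence-time and population-size estimates drastically — the
  performance script shows this arm for completeness, and it is the reason
  the all-sites analysis is the recommended design.

## Numerical choices

Matrix exponentials use cached eigendecompositions of the dense (m, j)
generator (falling back to scipy's expm if reconstruction error exceeds
1e−9); root absorption vectors and merge matrices are cached per θ_root.
Likelihoods accumulate in log space per pattern.  Gamma-hyperprior
marginals integrate adaptively (relative tolerance 1e−8) over the
hyperprior's 1e−14…1−1e−14 quantile range, so near-point-mass hyperpriors
are not missed; Monte-Carlo versions default to 10⁶ draws.  Partitions are
canonicalized by first-appearance order.  Degenerate posterior
probabilities (0 or 1 from finite samples) are replaced by one-pseudo-
sample bounds and flagged before odds are formed.  Credible intervals are
equal-tailed; the τ point estimate is the posterior mean; the estimated
number of events is the posterior mode with ties broken toward smaller k.
Sites with zero sampled copies in both populations are dropped with a
logged count.  A zero split time is clamped to 1e−12 when building msprime
demographies (the simulator cannot sample from an already-merged deme).

## Design choices made where the design was open

* The partition move is Neal-style auxiliary-variable Gibbs; any
  invariant-preserving scheme is acceptable and this one is validated by
  the prior-recovery and grid-posterior oracles.
* Burn-in counts the initial state as the first sample.
* Gamma priors are written (shape, mean) for θ and the root multiplier and
  (shape, scale) for α, with explicit config keys for each form.
* The serialization of binary loci writes each column with its first
  observed allele as 'A', so write→read round-trips reproduce pattern
  tables exactly (the model is invariant to the relabeling either way).
* Nucleotide diversity is computed from the recoded binary patterns; under
  the symmetric model this equals the per-site mismatch fraction of the
  original data except at recoded polyallelic sites.

## Limitations

No migration, no recombination within loci, constant sizes per branch, a
strict molecular clock shared across comparisons, and two-state characters
— all inherited from the model being implemented.  The sampler is a
single-machine, single-process implementation without checkpointing or
parallel tempering.  Credible-interval calibration under heavily linked
loci is the documented trade-off above.  Empirical RADseq idiosyncrasies
(acquisition bias, allele dropout) are outside the simulator's scope.
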
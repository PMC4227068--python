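# Methods

This note records the model conventions, numerical choices, and
experiment designs behind `codivabc`, and what the simulation-based tests
do and do not establish.

## Time scale and rate conventions

Divergence times τ and all node heights are in coalescent units of a
*reference* population of mutation-scaled size θ_C, defined as the
expectation of the prior on descendant-population size (for a U(0, b)
prior this is b/2, the half-the-upper-limit convention of the older
uniform-prior parameterization). One time unit is θ_C/μ generations
("4N_C generations"); `tau_to_generations` multiplies by θ_C/μ, so for
example τ = 10 with θ_C = 0.025 and μ = 1e-8 is 25 million generations.

Inside the simulator the pairwise coalescence rate in a population of
mutation-scaled size θ′ is 2 θ_C / θ′ per unit time, and branch lengths
convert to expected substitutions per site by multiplying time by θ_C.
These two choices are what make E[pairwise coalescence time] = 0.5 for a
population at θ_C and E[π] = θ′ exactly, consistent with θ = 4Nμ. The
test suite cross-checks the resulting genealogy law against msprime on
matched demographies (constant-size and bottleneck-plus-growth), mapping
a population of size θ′ to a diploid msprime population of size
θ′/(4 θ_C).

Locus-level scalings ρ (ploidy/generation time), ν (relative rate), and
the random multipliers υ_j ~ Gamma(α, 1/α) multiply *population sizes*,
which is equivalent to scaling that locus's θ; reported locus-scaled
divergence times instead use `scale_divergence_time`
(T θ_C / (θ̄_D ρ)). Whether the legacy implementation also folds ν and υ
into that reported rescaling is ambiguous; we scale sizes by ρ·ν·υ and
the reported per-locus times by ρ only, and note the residual ambiguity
here.

## Demography

Pastward from the present, each descendant population (i) shrinks
exponentially from θ_D at time 0 to θ_D·ζ at τ_B·T (the forward-time
"bottleneck that ends a fraction τ_B of the way back"), (ii) stays at
θ_D·ζ until the divergence time T, and (iii) merges into the ancestral
population of size θ_A. The exponential phase's rate is fixed by its two
endpoints: β = −ln ζ / (τ_B T). ζ = 1 or τ_B·T = 0 degenerate to constant
size; ζ = 0 is rejected (infinite rate). Waiting times in the shrinking
phase are drawn by inverting the integrated hazard with `log1p`, which is
stable for the extreme β values that arise when ζ is tiny.

Migration, when enabled, is an independent exponential clock per lineage
at rate m per unit of 4N_C time (the unit convention is our choice; the
parameter is off in every experiment here, matching the study conditions,
so nothing downstream depends on it). Competing events are resolved in
time order with deterministic tie-breaking by event type then lineage
index; ties have probability zero but the rule keeps runs reproducible.

## Sequence simulation

HKY85 rate matrices are normalized to one expected substitution per site
per unit branch length at stationarity. The default sampler uses
**uniformization**: the number of jump-chain events on a branch of length
b over L sites is Poisson(μ_max · b · L) and each event applies one step
of the kernel I + Q/μ_max. This is exact (not an approximation) and fast
when branches carry few expected substitutions, which is the regime here
(per-site tree lengths of order θ ≈ 0.01–0.1). A closed-form
transition-matrix sampler (`method="matrix"`, via the symmetrized
eigen-decomposition of Q) is also provided; the tests verify it against
`scipy.linalg.expm` and verify that the two samplers generate identical
site-pattern distributions, so either can serve as a check on the other.

## Summary statistics

Per alignment: π (mean pairwise per-site difference over the pooled
two-population sample), Watterson's θ_W = S/(a_{n−1} L), Nei's net
divergence π_net = π_b − (π_1 + π_2)/2, and SD(π − θ_W), the square root
of the Tajima (1989) variance estimator e1·S + e2·S(S−1), divided by L
(per-site). Pooling π/θ_W/SD over both populations, and the per-site
convention for the SD term, are conventions we fixed; both are applied
identically to observed and simulated data, so rejection rankings are
unaffected by the choice. Missing data (gaps, IUPAC ambiguities) are
excluded pairwise, with L the per-pair comparable length averaged where a
single L is needed; simulated data are complete and take a vectorized
path over segregating columns only.

Summary vectors hold four statistics per pair, optionally averaged across
loci, and either preserve pair order ("ordered", for ordered-model
inference) or are re-sorted by non-increasing π_b with stable ties
("pi_b_sorted", the unordered-model layout). The experiments below use
the sorted layout with a homogeneous data structure, under which the
blocks are exchangeable and the re-sort is valid.

## Priors and draws

Gamma distributions use the shape–scale convention (mean = a·b);
exponential(mean m) is gamma(1, m). Helpers construct moment-matched
pairs: an exponential with the variance of U(0, b) has mean b/√12
(2.887 for b = 10; 0.577 for b = 2), and U(0, m√12) matches the variance
of an exponential with mean m (34.64 for m = 10). s²_T is the population
(divide-by-Y) variance, recorded so either convention can be compared
downstream. χ (DPP concentration) and α (rate-heterogeneity shape) are
redrawn for every prior sample. The legacy joint descendant-size mode
draws the *mean* size uniformly and splits it by a Beta(1,1) fraction,
reproducing the negative correlation between θ_D1 and θ_D2 that the iid
gamma mode removes.

The U-shaped prior is sampled by drawing |τ| uniformly and rejecting
symmetric-multinomial assignments with empty classes (batched); since all
surjections are equally likely and each set partition with k blocks has
k! of them, the induced ordered-model pmf is exactly (1/Y)/S(Y, k), which
the tests use as the closed-form oracle for the U shape.

Regression adjustment uses weighted local-linear regression
(Epanechnikov weights 1 − (d/ε)², bandwidth the realized tolerance ε)
rather than delegating to an external GLM tool; the two are known to
behave very similarly and the local-linear form is self-contained.
Support-bounded parameters are adjusted on log (positive) or logit
((0,1)) scales, but only when every retained value is strictly interior —
s²_T and D_T are exactly zero whenever a retained draw has one divergence
event, so they are adjusted on the raw scale and clipped to ≥ 0. Discrete
model quantities (|τ|, the partition) are never adjusted; their
retained-sample frequencies are the model-probability estimates.

## Experiment designs and scales

Both harnesses run at desk scale by default, preserving the structure of
the full-scale designs while shrinking the Monte-Carlo sizes; all sizes
are parameters.

**Calibration** (`run_calibration`): with the analysis prior also
generating the data, simulate a shared prior table, then fresh replicate
datasets; analyze each by rejection and bin the estimated posterior
probability of one divergence event (by |τ| = 1 and by D_T < 0.01) into
20 bins of width 0.05 against the fraction of replicates in the bin where
the criterion is true. Because the ABC posterior probability is a proper
conditional probability of the event given (coarsened) data, the binned
points should track the identity line when the prior is correct; the
acceptance test checks every bin with ≥ 20 replicates against the exact
binomial 99% band around the bin midpoint. Defaults: 4 pairs, 2×10⁴ prior
draws, 500 replicates, 200 retained (1% of the prior sample), one 1000-bp
locus per pair with 10 genome copies per population, κ = 1 with equal
base frequencies (any ϕ works here since data and analysis share it).

**Power** (`run_power`): datasets are generated with *no* clustering —
every pair its own divergence time, drawn iid from a stated distribution
such as U(0, 2) — and analyzed under one or more priors. The dataset
stream depends only on the master seed, so different analysis priors see
byte-identical datasets. Reported per replicate: the MAP number of
events, p(|τ| = 1), p(D_T < 0.01), and the posterior-median D_T; the
headline rate is the fraction of replicates whose estimated D_T falls
below 0.01 (spurious co-divergence). Defaults: 8 pairs, 2×10⁴ prior draws
per analysis model, 200 replicates, 200 retained. The DPP analysis keeps
χ ~ Gamma(2, 2), the hyperprior appropriate for an 8-pair structure (the
much flatter Gamma(1.5, 18.1) used with 22 pairs would be miscalibrated
here). At these settings, with data from τ ~ U(0, 2), the DPP analysis
shows a spurious-clustering rate no higher than the U-shaped analysis on
the same datasets — the directional ordering the method is designed to
achieve — and the acceptance test asserts exactly that inequality.

One master seed spawns fixed sub-streams (prior = 1, datasets = 2) via
`numpy.random.SeedSequence`, so every experiment output is reproducible
bit-for-bit from (config, seed).

## What the synthetic data do and do not show

The generator produces gapless, equal-length, single-partition loci with
known ϕ, ρ, ν and no recombination, selection, or post-divergence gene
flow through the ancestral population. Calibration under a correct prior
is therefore a *self-consistency* property: it validates the estimator
and the simulator jointly, not robustness to model misspecification.
Real data add alignment error, missing sites (handled by pairwise
deletion, but at some cost in information), among-site rate variation,
recombination within loci, and — critically — non-exchangeable pairs,
for which the π_b-sorted layout is not valid and ordered-model inference
should be used. Power results at 8 pairs and one locus understate what
multi-locus data can resolve and should be read as orderings among
analysis priors, not absolute detection rates.

## Known limitations

* Intra-locus recombination is accepted in the config schema but
  rejected at runtime; all supported analyses assume r = 0.
* The four summary statistics carry little information about bottleneck
  and migration parameters; their posteriors are prior-dominated.
* Rejection ABC with a shared prior table reuses the same table across
  calibration replicates; at 2×10⁴ draws the induced dependence between
  replicates is negligible for binomial banding but is not zero.
* The partition-probability estimates for ordered models need far larger
  retained samples than |τ|-level summaries; with the default 200
  retained draws, per-model probabilities for Y ≥ 8 are noisy.
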
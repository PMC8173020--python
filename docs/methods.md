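# Methods

## Model structure and assumptions

All three systems share the same life cycle: random mating among census
adults, non-overlapping discrete generations, infinite population
(deterministic layer), no sex structure, no density dependence. The
census is taken on offspring **after** viability selection, and genotype
fitnesses are applied once per generation, to the offspring cohort.
Under this convention the extreme-underdominance recursion

    p' = p²(1−s) / (p²(1−s) + (1−p)²)

is exact: `TT × TT` matings are the only source of viable construct
offspring (`Tt` dies), and the surviving `TT` zygotes are weighted by
`1−s` exactly once. Applying the cost to *parents* instead would weight
`TT × TT` matings by `(1−s)²` and change every threshold; the
single-application convention is the one consistent with the closed-form
unstable equilibrium `p* = 1/(2−s)`.

Fitness costs in the comparative systems are additive per construct
copy, anchored so the released homozygote carries cost `s`:

- translocation: `w(TT) = 1−s`, `w(Tt) = 1−s/2`, `w(tt) = 1`;
- two-locus: `w = 1 − s·c/4` with `c` the number of construct alleles
  (0–4).

Mechanics: translocation heterozygotes produce ½ balanced gametes
(¼ `T`, ¼ `t`) and ½ unbalanced; any zygote formed from an unbalanced
gamete dies. The two-locus system assorts gametes independently at two
unlinked loci and kills every zygote carrying at least one copy of one
construct and none of the other. Both steps are implemented via pooled
gamete frequencies (valid under random mating) and are tested against
brute-force oracles that enumerate every mating pair × gamete pair ×
zygote outcome.

A release at frequency `f` replaces the adult pool with `f` construct
homozygotes and `1−f` wildtype; no cost is applied at the release census
itself (released adults are already viable).

## Thresholds and fates

A trajectory's fate is read off its final state: FIXED when the carrier
frequency (all genotypes with ≥1 construct allele) reaches `1 − 10⁻³`,
LOST below `10⁻⁶`, PERSISTING otherwise — a trajectory parked at the
unstable equilibrium is PERSISTING. Release thresholds are bisected to
`10⁻⁴` over 500-generation runs; both tolerances resolve every
threshold of interest to three significant figures. The no-spread guard
probes `f → 1` from below, because `f = 1` exactly is a monomorphic
construct population and trivially absorbing for every cost.

`max_invadable_cost` bisects over `s` with an establishment criterion —
a near-saturation release (`f = 1 − 10⁻⁶`) retains a carrier majority
after 1000 generations — rather than strict fixation. The distinction
matters for the two-locus system: between costs of roughly 0.47 and
0.73 it equilibrates at a stable internal polymorphism with ~96%
carriers (rare wildtype alleles are individually favored in a construct
background but purged when they meet), so "cannot spread" means
elimination, not incomplete fixation. Near the boundary the dynamics
slow critically; the 1000-generation horizon locates the translocation
and two-locus bounds to well under one percentage point, which is the
scale of the residual convention uncertainty anyway. For extreme
underdominance the function returns 1.0: `1/(2−s) < 1` for every
`s < 1`, so some release always spreads and no finite bound exists.

## Migration

Two equal-size demes exchange a fraction `m` of individuals per
generation; the order is migrate adults → mate → census offspring. The
mixing step alone conserves construct alleles exactly, and `m = 0`
reproduces isolated single-population trajectories bit for bit. The
source model holds an external population fixed for the construct and
replaces a fraction `m` of the sink with construct homozygotes each
generation.

The *sink equilibrium* (leak into an unreleased neighbor) is computed
from a fresh release in deme A (default 60%) iterated until successive
changes fall below `10⁻¹²`. The *loss-of-confinement threshold* is a
property of the established state: the construct first fixes in deme A
(which a supra-threshold release achieves under the low migration rates
where confinement is relevant), and the bisection on `m` asks when that
configuration stops being confined. Starting the bisection from the raw
60% release instead conflates two different questions — whether the
construct can establish *while* migration dilutes the release, and
whether an established drive persists — and gives a much lower, and
different, critical rate. Supercritical outcomes differ by system:
extreme underdominance and translocations are lost from both demes by
dilution; the two-locus system, with its low (~27%) threshold, instead
fixes in both demes once the leak can establish.

## Stochastic cage model

Finite cages are modeled as a Markov chain on counts: given the realized
construct frequency at generation `k`, the deterministic map gives the
expected frequency at `k+1`, and the whole next generation is a single
`Binomial(N, p)` draw (constant census `N`, no individual-based mating).
Defaults are `N = 50` and 10 replicates for model predictions; replicate
`r` uses an independent generator seeded `seed + r`, so any replicate is
reproducible in isolation.

## Synthetic cage studies

The generator emulates the cage-trial design the inference is meant for:
releases of {50, 70, 80, 90}% construct homozygotes, ≥3 replicates per
release, starting populations of 100 adults tracked for up to 11
generations, with generation-0 counts set exactly to `round(N·f)`. Every
later generation uses the constant-`N` binomial chain above. Features of
real cages deliberately not simulated: census-size fluctuation,
fluorescence scoring error, sexing, and (by default) replicate attrition
— an optional dropout probability truncates cages at a random
generation. Passing recovery tests on these data therefore validates the
estimator under the model's own noise structure, not under real-world
scoring or husbandry artifacts.

## Fitness-cost inference

The likelihood treats each observed generation `k ≥ 1` as a binomial
draw whose success probability is the one-generation map applied to the
*observed* census at `k − 1` (one-step-ahead prediction). This is the
exact factorized likelihood of the binomial chain above. Iterating the
map deterministically from generation 0 instead would treat accumulated
drift as observation noise; near the unstable threshold, where replicate
cages genuinely diverge (some fix, some are eliminated from the same
release), that misspecification biases the estimate and collapses
interval coverage. Generation-0 counts are conditioned on and contribute
nothing. Impossible observations (e.g. wildtype reappearing after a
census with no wildtype) yield `−∞`, not an exception; the fitter raises
a diagnostic naming the offending record only when no admissible cost
has finite likelihood.

The sampler is a 1-D Metropolis–Hastings random walk: uniform prior on
`[0, 0.99]` (the model degenerates at `s = 1`), Gaussian proposal
reflected at the bounds (reflection keeps the kernel symmetric), 10⁵
iterations, 10⁴ burn-in, thinning 10. During burn-in the proposal scale
adapts in windows of 200 toward a 0.4 acceptance rate — the random-walk
optimum for one-dimensional targets — and is then frozen, so the kept
chain is plain Metropolis. Initialization is the coarse-grid maximum-
likelihood point. The point estimate is the posterior median; the
credible interval the 2.5–97.5 percentiles. On synthetic reference
studies the 95% interval covers the generating cost in ~19 of 20 seeded
repetitions and post-burn-in acceptance sits near 0.4.

## Numerical choices and degenerate inputs

- Frequencies are clipped and renormalized to machine precision after
  every step; states must arrive normalized to `10⁻⁸` or are rejected.
- `s = 1` is rejected everywhere (zero denominator at fixation).
- Migration rates above 0.5 are rejected in the reciprocal model (more
  than half-exchange is not "migration" between distinct demes).
- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; identical seeds give bit-identical outputs.

## Known limitations

- No sex structure, age structure or density dependence; cage data with
  strong crowding effects would violate the constant-`N` chain.
- The comparative-system cost placement (additive per copy, offspring
  census) is one defensible convention; published simulation values for
  those systems vary by up to ~1 percentage point under alternative
  conventions, and computed thresholds should be read with that
  uncertainty. Under our convention translocations reach 99% carriers
  in 6–11 generations from a 65% release (costs 0–20%), one generation
  faster at the low-cost end than some published accounts.
- Only the extreme-underdominance system is fitted to count data; the
  comparative systems have no single scalar frequency, and cage data
  for them would need a genotype-resolved likelihood.
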
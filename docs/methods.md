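# Methods

## The model

Each genotype is an `N x N` real matrix `A` of regulatory interactions among
`N` genes (transcriptional regulators); element `a_ij` is the effect of gene
`j` on gene `i`. A fixed boolean mask with `round(c*N^2)` entries defines
which interactions exist (connectance `c`); topology is immutable — mutation
and recombination change only interaction strengths and signs.

Development iterates the synchronous recurrence

    s_i(t+1) = f( Σ_j a_ij s_j(t) ),      f(x) = 2/(1 + e^(-a x)) - 1,

for 100 steps from a founding expression state `s0`. Expression levels live
in (-1, +1): +1 is complete activation, -1 complete repression; the gain `a`
sets how sharply regulatory input switches expression. Stability is judged
on the last 10 states: with `S_ave` their elementwise mean and
`D(S, S') = Σ_i (s_i - s'_i)^2 / (4N)` (normalized so opposite saturated
states are at distance 1),

    V = (1/10) Σ_t D(S(t), S_ave).

A genotype is developmentally viable iff `V < 1e-4`; oscillatory or chaotic
expression is lethal. The phenotype `S_p` is the state at the final step.

Evolution proceeds in non-overlapping generations. Populations of 250
genotypes share one topology and one founding state `s0` (drawn once per
lineage, uniform per gene on [-1, 1]), so phenotype differences within a
lineage reflect genotype alone. Each generation a pool of exactly 1000
viable offspring is assembled: sexual reproduction pairs two distinct
uniformly drawn parents and copies each matrix row whole from one parent or
the other with probability 1/2 (cis-regulatory elements tightly linked to
their gene); asexual reproduction clones one parent. Each non-zero element
then mutates independently with probability `mu/(c N^2)` (`mu = 0.1` per
genome, i.e. 0.1 expected mutations per offspring and 100 entering each
pool), receiving a fresh standard-normal value. Inviable offspring are
discarded and redrawn. The 250 offspring with the highest fitness
`F = exp(-D(S_p, S_opt)/sigma)` (`sigma = 0.05`) survive; survival is purely
rank-based, so any strictly decreasing function of distance gives identical
trajectories. Ties are broken uniformly at random with the run's own stream.

The optimal phenotype `S_opt(t)` follows one of four schedules: constant at
the founding phenotype (stabilizing); the founding phenotype shifted by a
red-noise series `E(t)` and clipped elementwise to [-1, 1]; the same with a
white permutation of the series; or a fixed displaced target (directional).
Red noise is synthesized as

    E(t) = Σ_{f=1..⌊n/2⌋} f^(-γ) sin(2π f t / n + θ_f),

with phases `θ_f ~ U[0, 2π)` drawn once per series and the series divided by
its maximum absolute value so it spans [-1, 1] exactly. `n` is the period of
the dominant (largest-amplitude) wave and `γ = 1` produces strongly
autocorrelated, near-sinusoidal noise. White series are exact random
permutations of a full-length red series: identical value multiset,
autocorrelation destroyed. Directional targets sample a period-50 red series
at `t = 5, 10, 15, 20, 25` (even intervals across half a period), so they
span displacements comparable to what fluctuating selection imposes.

## Assays

*Mutation accumulation.* For `m = 1..6` (an expanded 1..50 mode exists), 50
replicate mutants per level receive `m` distinct non-zero elements redrawn
from the standard normal, then develop from the lineage `s0`. Recorded per
level: the percentage viable `W_m` and the mean Euclidean distance between
pre- and post-mutation phenotypes among viable mutants (inviable mutants
have no phenotype, so distance is defined over viable ones only). Viability
responses are fitted with `ln(W_m) = -α m^β + ln(100)` via OLS of
`ln(ln(100) - ln(W_m))` on `ln(m)`; distance responses with
`W_m = α m^β` via OLS on the log-log scale. `β` is the directional-epistasis
exponent (`β > 1` synergistic, `β < 1` antagonistic), `α` the
single-mutation effect. Viability robustness is `W_1 = 100 e^(-α)`;
phenotypic robustness is `1/W_1 = 1/α` of the distance fit. Observations at
exactly 0% or 100% are undefined under the log transform; by default they
are moved half an observation inside the scale (`100/(2R)` and
`100(1 - 1/(2R))` for `R` replicates) so they remain usable — interior
values are never altered, and the replacement can be disabled, in which case
boundary points are dropped.

*Evolvability.* A network is cloned into a fresh population of 250 and
selected for four generations by the standard engine (pool 1000, `mu = 0.1`)
toward a random target phenotype (elements uniform on [-1, 1]; repeated for
10 targets). The rate of adaptation is the negated pooled OLS slope of
`ln(distance to target)` on generation index over all members and
generations 0–4, with distances floored at 1e-6 before logging; the
production of phenotypic variation is the SD of member distances averaged
over the four post-selection generations. Both are averaged across targets,
which suppresses between-seed variance roughly in proportion to the number
of targets.

*Population metrics.* Allelic diversity: mean number of distinct weight
values per non-zero locus (exact floating comparison — values arise only by
copy or fresh draw, so equality is meaningful; a rounding knob exists for
external data). Phenotypic diversity: count of distinct phenotype vectors.
Matrix change: fraction of (member, locus) weights differing from the
founder. Interaction profile: for off-diagonal elements the realized signed
effect is `a_ij * s_j` with `s_j` the member's own phenotype (the sign of a
regulatory effect depends on the expression of the regulator); strength is
the mean absolute effect and `prop_positive` the fraction strictly positive
(zero effects count as non-positive, a measure-zero event). Per-generation
mean log fitness of survivors is always recorded; its trailing mean is the
geometric-mean-fitness measure relevant in fluctuating environments.

## Numerical and design choices

- **Batched development.** The engine develops whole offspring batches at
  once (stacked matmul over `(B, N, N)` weights); a per-gene loop oracle in
  the test suite confirms agreement to 1e-12. Trajectories whose 10 tail
  states are bit-identical are assigned `V = 0` exactly, clearing the
  rounding residue of the mean subtraction so "fixed point" and `V = 0`
  coincide.
- **Log-space fitness.** Selection and reporting use `log F = -D/sigma`
  directly, avoiding `exp` underflow at large distances; rank order is
  unchanged.
- **Pool filling.** Candidate batches are sized by a running viability
  estimate; a cap of 100x the pool size converts unfillable pools (e.g.
  pathological mutation pressure) into a diagnosable meltdown error carrying
  the generation index.
- **Random streams.** One master seed per run is split (via SeedSequence
  keyed by a CRC32 of a component label) into independent founder / noise /
  evolution / assay streams, so changing assay cadence cannot perturb the
  trajectory, and every run is bit-reproducible from (config, seed).
- **Optimum shifts.** The scalar noise value is added to every gene of the
  founding phenotype — one shared environmental variable; per-gene series
  are accepted as an option (a `(T, N)` noise array) but are off by default.
- **Stability convention.** `V` averages the 10 tail deviations; a summed
  variant is exposed (`reduce="sum"`), but the 1e-4 threshold is calibrated
  to the mean convention and is kept with it.
- **Assay battery during runs.** `run_simulation` always records population
  metrics and mean log fitness at the assay cadence (every 2000 generations,
  optionally every 50 up to generation 500). The per-network mutation and
  evolvability assays multiply runtime by roughly two orders of magnitude,
  so they are opt-in config flags; the `assays` module functions are the
  first-class interface for those measurements on sampled or stored
  networks.

## What the generator emulates, and what it does not

The simulated conditions are the model's standard ones: 10-gene networks at
connectance 0.75 (75 interactions), standard-normal weights, gain `a = 1`,
`sigma = 0.05`, `mu = 0.1`, populations of 250 from pools of 1000, noise
exponent `γ = 1`, dominant periods 10/30/50/70. All genotypes arise
internally by rejection sampling of developmentally stable random networks —
there is no external data. The model abstracts away phenotypic plasticity,
environmental perturbation of development, diploidy, spatial structure and
evolvable topology; passing tests therefore speak to the evolutionary logic
of this idealized genotype–phenotype map, not to any particular organism.
Phenotypic variation equals additive genetic variation here precisely
because plasticity is absent.

## Problem sizes used in the shipped checks

The test suite and acceptance script run desk-scale versions of the full
experiments: founder ensembles of 25 networks with 50 replicate mutants per
mutation level (the full assay design), and evolutionary runs of 2000
generations at dominant period 50 with three seed replicates per regime
rather than 36000 generations with 25 populations. At that scale the
qualitative orderings (diversity accumulation under fluctuating selection;
red-noise geometric mean fitness above the matched white control) are large
relative to seed noise. Ensemble means of slowly equilibrating quantities
(robustness, epistasis) at 2000 generations are not expected to match
36000-generation time averages quantitatively.

## Known limitations

- The closed forms of the sigmoid, the distance `D`, the fitness function
  and the noise amplitude law follow the conventions of this model family;
  where a convention is genuinely open (e.g. the amplitude exponent `γ` vs
  `γ/2`), the choice is isolated behind one function and configurable.
- Measured at these settings, six random element replacements leave roughly
  half of fresh stable networks viable; mutational lethality rises sharply
  with the sigmoid gain (tests and the acceptance script report the value
  actually computed at the default gain).
- Exact-equality diversity metrics assume weights propagate only by copy or
  fresh draw; data filtered through lossy text formats should use the
  rounding knobs.
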
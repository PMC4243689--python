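# Methods

`basepop` simulates the construction of an aquaculture-style breeding
program from scratch — neutral equilibrium population, divergent candidate
strains, optimised founder selection, and a phenotypic selection program —
and measures what each founder-selection strategy buys in trait performance
and genome-wide diversity. This note records the model, the defaults, and
the choices made where the design was genuinely open.

## Genome and equilibrium population

Individuals are diploid with `n_c` chromosomes of 1 Morgan, each carrying
evenly spaced biallelic loci of two kinds: *non-marker* (neutral) loci used
to measure diversity, and *marker* loci (SNP-like) used by the optimiser.
Markers sit at evenly spaced ranks among all loci, so a sparser panel is a
subset of a denser one whenever one panel size divides the other.

The founder population starts at allele frequency 0.5 everywhere
(Hardy–Weinberg and linkage equilibrium by construction) and evolves under
random mating with recurrent symmetric mutation: the number of allele flips
per generation is Poisson with mean `2 N n_c mu n_l` (`mu = 2.5e-3` per
locus per generation), targets uniform over allele copies. Meiosis places a
Poisson(1) number of crossovers per chromosome uniformly, without
interference, with a uniformly chosen starting strand.

Two implementation notes:

* For whole-cohort reproduction the crossover process is simulated in its
  interval representation: the total crossover count over all
  (gamete, inter-locus interval) cells is Poisson, positions are uniform,
  and the source strand toggles with the parity of events per interval.
  This is the same stochastic process read out at the loci (Haldane
  mapping), at a fraction of the cost. The single-gamete routine keeps
  explicit crossover points so degenerate cases can be forced in tests.
* Expected heterozygosity under mutation–drift balance obeys the recursion
  `Q' = a(1/(2N) + (1-1/(2N))Q) + b(1-1/(2N))(1-Q)` with
  `a = (1-mu)^2 + mu^2`, `b = 2mu(1-mu)`; the package exposes the fixed
  point (`equilibrium_heterozygosity`) and the simulator is validated
  against it at reduced N. At N = 1000 the fixed point is He ≈ 0.476; at
  N = 100, He ≈ 0.334.

## Trait model

A single additive trait with mean 100, initial phenotypic variance 30 and
heritability 0.4 (`V_A(0) = 12`) is controlled by `n_sel` loci drawn
uniformly from all loci (markers included). Effects are i.i.d.
`Normal(0, V_A(0) / [2 p (1-p) n_sel])` where `p` is the mean allele-1
frequency over the chosen loci at the moment the trait is defined (once per
replicate, right after burn-in). Phenotypes are
`P = 100 + sum_i x_i a_i + e`, with `x_i` in {-1, 0, +1} and
`e ~ N(0, V_E)`.

`V_E` is calibrated per strain at its founding from the *realised*
genetic variance, `V_E = V_A,strain(0)(1-h2)/h2`, and then held fixed, so
every strain starts at h² = 0.4 exactly and heritability drifts with V_A
afterwards. Breeding values are reported as deviations from the
pre-divergence cohort mean, so unselected scenarios start near zero.

A caveat worth knowing: with the printed calibration the expected summed
additive variance is `V_A(0) · mean(2p(1-p)) / (2 p̄ (1-p̄))`, which is only
≈ `V_A(0)` when allele frequencies cluster near their mean. That holds at
the full-scale equilibrium (4Nμ = 10); at small-N equilibria the frequency
distribution is U-shaped and realised V_A falls below 12. The calibration
check therefore uses a Hardy–Weinberg cohort at p ≈ 0.5.

## Strains and scenarios

Ten strains are founded disjointly from the equilibrium population and
diverge for 20 mutation-free generations under one of three regimes —
drift (random selection), directional (top-`k` per sex on phenotype), or
stabilizing (Gaussian viability `W(P) = exp(-(P-P_opt)²/2ω²)`, ω² = 5,
survivors mate at random; if a sex class has no survivors, parents are
drawn proportionally to W). Four scenario presets (drift / selection /
stabilizing / mixed) encode the per-strain sizes, selection pressures and optima for each scenario;
`stabilizing_large` carries the 20-per-sex variant mentioned in prose, and
`four_strains` is an approximate small-candidate-set illustration. Each
strain then expands to 50 males + 50 females in one generation of random
mating; candidates receive their phenotypes at this point and keep them.

## Coancestry and diversity

Molecular coancestry is identity-in-state kinship: the probability that one
allele drawn from each of two individuals at a random marker matches,
computed from dosages as `q_i q_j + (1-q_i)(1-q_j)` averaged over loci
(no allele-frequency correction). Averaged over a group including
self-pairs it satisfies `group coancestry = 1 − He` exactly on the same
loci — the identity that makes minimising group coancestry equivalent to
maximising expected heterozygosity, and the reason strain-mean blocks
include self-pairs. Pedigree inbreeding/coancestry use the tabular method
with base-population founders treated as unrelated and non-inbred; rates
are `Δx_t = (x_t − x_{t-1})/(1 − x_{t-1})`. Reported mean coancestry of a
group excludes self-pairs (so founders start at f = 0); group coancestry
*for the optimiser's constraint* includes them, matching the identity
above.

## Founder selection

From 1000 candidates (10 strains × 50 + 50), each strategy picks 100 males
and 100 females:

* **E** — equal numbers per strain at random; its realised marker group
  coancestry defines `C_E`.
* **MC** — strain proportions minimising `c'Fc` over strain-mean
  coancestries; **MP** — maximise `c'P̄` subject to `c'Fc ≤ C_E`.
  Proportions are rounded to the nearest even counts (largest-remainder
  repair in ±2 steps, ties to the lowest strain index, availability caps
  respected), then individuals are sampled at random within strains, half
  per sex.
* **IC** — binary selection minimising `x'Fx` over individual
  coancestries; **IP** — maximise `Σx_iP_i` subject to the group coancestry
  cap at `C_E`.

All searches use simulated annealing with geometric cooling
(`T_k = T0·α^k`), a same-sex swap move for subsets and a mass-transfer move
for proportions, seeded from the strategy-E solution (subsets) or the MC
solution (MP). `T0` is set from the spread of *objective* deltas over 100
random moves — using full penalised-energy deltas would inflate `T0` by the
penalty scale (`λ = 10⁶ ×` phenotype range) and freeze the search; this was
measurable as a ~6-unit loss in IP mean phenotype. Constraints are enforced
by that penalty plus a final feasibility check; the best feasible state is
tracked throughout. Continuous solutions get a deterministic greedy polish
(pairwise transfers over a decreasing step ladder), which pins the optimum
to ~1e-4. An SLSQP route (`method="slsqp"`) provides an exact cross-check
for the continuous problems, and exhaustive enumeration verifies the subset
problems on small instances. Defaults: α = 0.995, 200 moves per
temperature, stop after 50 idle temperatures, 3 restarts; the desk-scale
experiment preset uses a lighter, configurable schedule (α = 0.99,
patience 40, 1 restart) that reaches the same optima on desk-sized
instances.

Degenerate cases: if `C_E` lies below the unconstrained minimum of `c'Fc`,
MP returns the MC solution with a warning; if IP finds no feasible state,
it returns the best penalised state flagged infeasible. Ties in the MP
objective break toward lower coancestry via a tiny secondary term.

## Breeding program

Selected founders (keeping their candidate-phase phenotypes) are paired
into 100 monogamous couples by a uniform random perfect matching; each
couple leaves 10 offspring (sexes alternating within family so both sex
classes stay exactly half); the top 100 per sex on phenotype breed the next
generation, for 10 generations — a 20% selected proportion, intensity
≈ 1.40. Offspring phenotypes use one program-level environmental variance,
the mean of the founders' strain-calibrated `V_E` values (cohorts mix
strains, so per-strain variances no longer apply); it stays fixed across
generations. Per generation the selected group's mean phenotype, mean
breeding value, additive variance (divisor n), non-marker He, and pedigree
F and f are recorded; kinship is propagated recursively
(`f(o,o') = ¼ Σ` parental kinships, diagonal `(1+F)/2`), which equals the
tabular method on the accumulated pedigree (asserted in tests).

## Scale presets and what the tests show

`full_plan` carries the full-scale conditions (20 × 25,000 + markers,
N = 1000, 1000 burn-in generations, 100 replicates) and is intended for
cluster runs. `desk_plan` is the scale at which the test-suite and the
acceptance script run: 10 chromosomes × (200 non-marker + 500 marker) loci,
N = 400, 150 burn-in generations, 500 selective loci, everything downstream
at full-scale values. The marker spacing (0.002 M) was chosen so that, at
the desk-scale effective population size, adjacent markers still tag
neutral loci appreciably (4Nc ≈ 2–3 between neighbours), preserving the
mechanism by which dense panels transfer a marker-coancestry constraint to
genome-wide diversity. A 5000-locus genome (480 + 20 per chromosome) is
used for the coancestry-rate checks, where marker density is irrelevant.

At this scale the pipeline reproduces the qualitative results: IC retains
the most non-marker He, IP and MP trade diversity for phenotype and IP
dominates MP when individual records are available, sparse panels let IP
erode non-marker He despite the marker-level constraint, neutral breeding
drifts at Δf ≈ 0.25% per generation and trait-driven selection pushes the
rate toward ≈ 0.4%, and V_A collapses between generations 0 and 1 (Bulmer
effect). Quantitative magnitudes (e.g. the IP phenotype advantage) are
smaller than at full scale because desk-scale strains start from a less
diverse equilibrium; the acceptance script reports the values the desk
scale actually produces.

What the synthetic data does *not* emulate: sequence-level realism
(nucleotides, variable recombination or mutation maps, interference),
dominance/epistasis, overlapping generations, mass spawning, genotyping
error or missingness. Passing tests therefore validate the method's
internal logic and its stated population-genetic behaviour, not performance
on any real dataset.

## Numerical choices

Allele data are uint8 (one byte per allele copy); coancestry and all
statistics are float64. Variance uses divisor n everywhere. Phenotype ties
in truncation selection break by ascending id; annealing tie-breaks are by
stable id order via the seeded move sequence. The uint8 parity cumsum in
meiosis wraps mod 256 (even), preserving parity exactly. Reproducibility:
one `SeedSequence` per (scenario, replicate) spawns independent child
streams for build, optimisation and breeding, so identical seeds give
bit-identical outputs.
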
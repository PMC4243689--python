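# basepop

Simulation and optimisation of **base populations** for aquaculture-style
breeding programs.

When a breeding program starts, all the genetic variability it will ever
select on is whatever its founders carry. `basepop` asks, by forward
simulation, how those founders should be chosen from a set of candidate
strains when genome-wide marker genotypes and/or phenotype records are
available — and what each choice costs or buys over the following
generations of selection.

The pipeline is:

1. **Equilibrium population** — a diploid genome (20 chromosomes × 1 Morgan
   at full scale) of biallelic neutral and marker loci evolves to
   mutation–drift equilibrium under random mating, recurrent symmetric
   mutation (μ = 2.5 × 10⁻³) and Poisson(1) crossovers per Morgan.
2. **Candidate strains** — ten strains sampled from it diverge for 20
   generations under drift, directional truncation selection, or Gaussian
   stabilizing selection `W(P) = exp(−(P−P_opt)²/2ω²)`, then expand to
   50 males + 50 females each.
3. **Founder selection** — 100 males + 100 females are chosen from the 1000
   candidates under five strategies: **E** (equal numbers per strain),
   **MC** / **MP** (strain proportions minimising the marker group
   coancestry `c'Fc`, or maximising mean phenotype `c'P̄` subject to
   `c'Fc ≤ C_E`), and **IC** / **IP** (the individual-level analogues
   `min x'Fx` and `max ΣxᵢPᵢ` under the same coancestry cap), where `C_E`
   is the coancestry realised by strategy E and `F` is identity-in-state
   kinship from the markers. The combinatorial problems are solved by
   simulated annealing.
4. **Breeding program** — 10 generations of phenotypic truncation selection
   (100 couples × 10 offspring, top 20% selected, intensity ≈ 1.4),
   tracking phenotype, breeding value, additive variance, non-marker
   expected heterozygosity, and pedigree inbreeding/coancestry with their
   rates.

The trait is additive: `P = μ_P + Σ xᵢaᵢ + e` with effects calibrated so the
founding additive variance is `V_A(0) = h²V_P = 12`, and per-strain
environmental variance fixed at founding so every strain starts at
h² = 0.4. A useful exact identity ties the two optimisation currencies
together: group IBS coancestry (self-pairs included) equals `1 − He` on the
same loci, so minimising coancestry *is* maximising expected
heterozygosity.

## Worked example

```python
import numpy as np
from basepop import desk_plan, load_scenario
from basepop.experiment_runner import run_replicate

plan = desk_plan(strategies=["E", "MC", "MP", "IC", "IP"],
                 marker_numbers=[5000], n_replicates=1)
tables = run_replicate(plan, load_scenario("mixed"), 0,
                       np.random.SeedSequence(1))
print(tables["base"][["strategy", "phenotype_mean", "he_nonmarker_pct"]])
```

```
  strategy  phenotype_mean  he_nonmarker_pct
0        E      105.914923         42.382618
1       MC      104.150235         42.950219
2       MP      108.471981         42.444036
3       IC      104.185063         43.147219
4       IP      113.818899         42.468551
```

One Mixed-scenario replicate with a dense marker panel: the equal-sampling
reference E starts the program at phenotype ≈ 105.9; exploiting individual
phenotypes under the same marker-coancestry budget (IP) lifts the founders'
mean by ~8 units while non-marker heterozygosity (in %) stays at the E
level; the pure-diversity strategies MC/IC give up phenotype to retain the
most heterozygosity. Averaged over 20 replicates the orderings sharpen:
He(IC) > He(MC) > He(E) ≈ He(IP), and phenotype(IP) > phenotype(MP) >
phenotype(E), with IP's advantage largest — at the cost of genome-wide
diversity — when only a sparse panel constrains it.

A command-line interface wraps the same machinery:

```bash
basepop run --config plan.yaml --out results/          # replicated experiment
basepop optimize --genotypes g.tsv --phenotypes p.tsv \
        --strategy IP --out solution                   # real-data founder choice
basepop summarize --input results/base.tsv --group scenario,strategy
```

`basepop optimize` accepts a TSV dosage matrix or a VCF plus a phenotype
table (`id  sex  strain  phenotype`), so the optimiser can be pointed at
real candidate data.

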
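# Approximate small-candidate-set scenario: four drift strains of 20
# individuals each (10 per sex).  Intended for use with a smaller
# equilibrium population (about 100 individuals) and a smaller base
# population (about 24 breeders); parameters not fully specified, treat as
# illustrative only.
name: four_strains
divergence_generations: 20
expansion_per_sex: 10
strains:
  - {strain_id: 1, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 2, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 3, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 4, regime: drift, n_males: 10, n_females: 10}
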
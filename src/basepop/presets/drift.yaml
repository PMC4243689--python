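# Drift scenario: all strains under random selection, differing in per-sex size.
name: drift
divergence_generations: 20
expansion_per_sex: 50
strains:
  - {strain_id: 1, regime: drift, n_males: 5, n_females: 5}
  - {strain_id: 2, regime: drift, n_males: 5, n_females: 5}
  - {strain_id: 3, regime: drift, n_males: 5, n_females: 5}
  - {strain_id: 4, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 5, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 6, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 7, regime: drift, n_males: 20, n_females: 20}
  - {strain_id: 8, regime: drift, n_males: 20, n_females: 20}
  - {strain_id: 9, regime: drift, n_males: 20, n_females: 20}
  - {strain_id: 10, regime: drift, n_males: 20, n_females: 20}
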
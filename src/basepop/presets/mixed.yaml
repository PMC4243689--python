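# Mixed scenario: drift, stabilizing and directional strains together.
name: mixed
divergence_generations: 20
expansion_per_sex: 50
strains:
  - {strain_id: 1, regime: drift, n_males: 5, n_females: 5}
  - {strain_id: 2, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 3, regime: drift, n_males: 10, n_females: 10}
  - {strain_id: 4, regime: drift, n_males: 20, n_females: 20}
  - {strain_id: 5, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 90, omega2: 5}
  - {strain_id: 6, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 100, omega2: 5}
  - {strain_id: 7, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 110, omega2: 5}
  - {strain_id: 8, regime: directional, n_males: 10, n_females: 10, n_selected_per_sex: 5}
  - {strain_id: 9, regime: directional, n_males: 10, n_females: 10, n_selected_per_sex: 3}
  - {strain_id: 10, regime: directional, n_males: 10, n_females: 10, n_selected_per_sex: 1}
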
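# Variant of the stabilizing scenario with 20 individuals per sex per strain.
name: stabilizing_large
divergence_generations: 20
expansion_per_sex: 50
strains:
  - {strain_id: 1, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 90, omega2: 5}
  - {strain_id: 2, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 90, omega2: 5}
  - {strain_id: 3, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 90, omega2: 5}
  - {strain_id: 4, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 100, omega2: 5}
  - {strain_id: 5, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 100, omega2: 5}
  - {strain_id: 6, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 100, omega2: 5}
  - {strain_id: 7, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 100, omega2: 5}
  - {strain_id: 8, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 110, omega2: 5}
  - {strain_id: 9, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 110, omega2: 5}
  - {strain_id: 10, regime: stabilizing, n_males: 20, n_females: 20, p_opt: 110, omega2: 5}
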
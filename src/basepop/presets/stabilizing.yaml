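# Stabilizing scenario: Gaussian viability selection toward strain-specific
# optima (strength omega^2 = 5), 10 individuals per sex.
name: stabilizing
divergence_generations: 20
expansion_per_sex: 50
strains:
  - {strain_id: 1, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 90, omega2: 5}
  - {strain_id: 2, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 90, omega2: 5}
  - {strain_id: 3, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 90, omega2: 5}
  - {strain_id: 4, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 100, omega2: 5}
  - {strain_id: 5, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 100, omega2: 5}
  - {strain_id: 6, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 100, omega2: 5}
  - {strain_id: 7, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 100, omega2: 5}
  - {strain_id: 8, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 110, omega2: 5}
  - {strain_id: 9, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 110, omega2: 5}
  - {strain_id: 10, regime: stabilizing, n_males: 10, n_females: 10, p_opt: 110, omega2: 5}
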
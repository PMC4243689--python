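# Selection scenario: equal sizes, directional selection of varying strength.
name: selection
divergence_generations: 20
expansion_per_sex: 50
strains:
  - {strain_id: 1, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 2}
  - {strain_id: 2, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 2}
  - {strain_id: 3, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 3}
  - {strain_id: 4, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 3}
  - {strain_id: 5, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 4}
  - {strain_id: 6, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 4}
  - {strain_id: 7, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 4}
  - {strain_id: 8, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 5}
  - {strain_id: 9, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 5}
  - {strain_id: 10, regime: directional, n_males: 20, n_females: 20, n_selected_per_sex: 5}
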
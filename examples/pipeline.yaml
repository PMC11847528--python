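# Scaled-down end-to-end configuration for `dyspredict run`.
n_parcels: 24
n_subjects: 8
n_patients: 16
bundles: 10
n_bundle_pairs: 50
permutations: 50
seed: 5
planted_r2:
  motor_left: 0.9
  motor_right: 0.6
  executive: 0.6
  processing_speed: 0.3
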
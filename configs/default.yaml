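# Study-scale cohort: two groups with the published demographics, group
# differences injected through the reluctance scenario (registration
# threshold 0.6 vs 0.2, all other agent parameters shared).
master_seed: 0
scenario: reluctance
autism:
  n: 43
  n_male: 35
  iq_mean: 105.0
  iq_sd: 13.4
  age_mean: 28.0
  age_sd: 9.0
control:
  n: 42
  n_male: 35
  iq_mean: 113.0
  iq_sd: 11.6
  age_mean: 26.0
  age_sd: 5.8
payoffs: {T: 5, R: 3, P: 1, S: 0}
rounds: {TFT: 20, WSLS: 20, AC: 10, AD: 10}
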
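# Demo pipeline: a scaled-down two-group tissue experiment with planted
# binding (5% of sequences) and differential binding (5%, 2.5-fold), followed
# by normalization, binding and differential calls, and the random-split
# noise control within the cancer group.
simulate:
  n_sequences: 1000
  seq_length: 1000
  spots_per_sequence: 10
  slides_per_group: [4, 8]
  n_groups: 2
  frac_bound: 0.05
  bound_effect: 1.0
  frac_differential: 0.05
  differential_effect: 1.3
  dye_bias_amplitude: 0.5
  slide_scale_sd: 0.1
  spot_noise_sd: 0.25
  seed: 11

normalize:
  span: 0.3
  quantile: ratio
  aggregate: median

diffbind:
  contrast: normal:cancer
  alpha: 0.05
  m_cutoff: 1.0

compare:
  split:
    group: cancer
    n: 4
    seed: 17

outdir: pbmkit_demo_run
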
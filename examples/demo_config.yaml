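# Small end-to-end demo configuration for the CLI:
#   nirsnet all --config examples/demo_config.yaml
seed: 11
out: scratch/demo_run
band: [0.02, 0.1]
surrogates: 30
aggregation: zero
cohort:
  n_subjects: 8
  fs: 4.0
  duration: 120.0
  noise_sd: 0.4
  drift_amplitude: 1.0
  oscillators:
    - {center_frequency: 0.05, fractional_bandwidth: 0.6, amplitude: 1.0}
  couplings:
    near:
      - {channel_pair: [CH18, CH19], strength: 0.9, band: [0.03, 0.08]}
    far:
      - {channel_pair: [CH18, CH19], strength: 0.3, band: [0.03, 0.08]}
  behavioral: {intercept: 50.0, slope: 30.0, residual_sd: 2.0}
preprocess:
  dct_cutoff_s: 60.0
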
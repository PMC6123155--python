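# Example configuration for `respsurro simulate` and `respsurro report`.
simulate:
  mean_period: 4.0       # s
  period_sd: 0.2
  mean_depth: 100.0
  depth_sd: 5.0
  plateau_exponent: 1.5  # end-of-exhalation dwell
  noise_sd: 0.0
  sampling_rate: 25.0    # internal-motion grid, Hz
  duration: 60.0
  seed: 1

distortion_a: {}         # displacement surrogate: faithful

distortion_b:            # pressure surrogate: leads and falls steeply
  lag: 0.2               # s; positive = reaches EOI earlier
  exhale_steepness: 1.5
  extra_noise_sd: 1.0

timeline:
  scan_start: 0.0
  scan_stop: 60.0
  beam_segments:
    - [5.0, 25.0]
    - [30.0, 55.0]

# cohort block used by `respsurro report`
cohort:
  n_patients: 5
  mean_period_range: [2.5, 5.6]
  lag_mean: 0.2
  lag_sd: 0.1
  exhale_steepness_range: [1.3, 2.0]
  noise_sd: 1.0

gate:
  mode: amplitude
  lower: 0.0
  upper: 30.0            # 0-100 normalized units; EOE-centred window
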
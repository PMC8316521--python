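# Demo pipeline run: fully synthetic correlative scene, single CPU, < 1 min.
schema_version: 1
seed: 7
out_dir: pipeline_out

simulate:
  shape: [64, 64]
  pixel_size: 107.0
  sigma0: 130.0
  frames: 600
  exposure: 0.05
  epsilon: 300.0
  tau_on: 3.0
  tau_off: 9.0
  n_background_emitters: 25
  emitters_per_feature: 3
  topography:
    n_microvilli: 6
    n_filopodia: 1
    dome_amplitude: 400.0

preprocess:
  skip_frames: 50
  drift_block_len: 0

cumulants:
  order: 2
  flatten: true

postprocess:
  deconv_iters: 10
  no_deconv: false

resolution:
  n_filters: 10

scan:
  pipette_radius: 50.0
  setpoint: 0.99
  hopping_height: 3000.0
  pixel_rate: 200.0
  noise_sigma: 2.0

register:
  jitter_px: 0.0

correlate:
  section_half_length_px: 6
  displace_factor: 2.0
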
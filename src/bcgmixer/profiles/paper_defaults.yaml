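# Frozen default profile: every value equals the study protocol where one is
# stated.  Override by copying this file and editing; unknown keys are rejected.
synthetic:
  n_hpt: 61
  n_nrt: 67
  duration_min: 50.0
  fs: 100.0
  params:
    hr_mean_hpt: 77.1
    hr_sd_hpt: 9.2
    hr_mean_nrt: 73.6
    hr_sd_nrt: 8.3
    hrv_jitter: 0.05
    amp_log_sigma: 0.5
    wander_freq: 0.2
    wander_amp: 0.5
    resp_mod_freq: 0.25
    resp_mod_depth: 0.2
    noise_sd: 0.1
    wavelet_center_hz: 5.0
    wavelet_width_s: 0.15
    separation_mode: realistic
preprocessing:
  filter: canonical      # the fixed published constants
  zero_phase: false
  window_s: 30.0
spectrogram:
  window_type: hanning
  window_len: 128
  overlap: 120           # 15/16 of 128
  nfft: 128
  scale: db_power
  threshold_db: -40.0    # relative floor; the one free imaging parameter
  colormap: viridis
  render_size: [420, 560]
  final_size: [224, 224]
model:
  patch_size: 5
  hidden_dim: 32
  depth: 7
  depthwise_kernel: 5
  prose_residual: false
training:
  learning_rate: 0.001
  momentum: 0.9
  batch_size: 64
  epochs: 7
  validation_fraction: 0.1
evaluation:
  k: 10
  grouping: image_level
protocol:
  trim_minutes: 50.0
seed: 0
out_dir: runs
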
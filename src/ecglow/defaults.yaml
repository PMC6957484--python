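# Central location for every numeric constant of the pipeline.
# Units are given per key; loaded by ecglow.config.load_config().

glucose:
  low_threshold_mmol_l: 4.0      # LGL: glucose < 4.0 mmol/L
  guard_band_mmol_l: 4.2         # training guard band: [4.0, 4.2) excluded
  normal_high_mmol_l: 7.5        # NGL upper bound
  eligibility_min_pct_below_guard: 10.0
  eligibility_p80_max_mmol_l: 7.5

cgm:
  interval_s: 900                # one interstitial reading every 15 min
  lag_s: 300                     # physiological sensor lag, ~5 min
  mard_pct: 11.4                 # mean absolute relative difference of the sensor

ecg:
  fs_hz: 250
  beat_window_pre: 60            # samples before the R peak
  beat_window_post: 100          # samples after the R peak (window = 160 total)
  downsample_k: 3                # keep every 3rd sample, offset 2 -> 53 points
  beat_series_len: 53
  refractory_ms: 200
  quality_window_s: 5
  quality_hr_bpm: [30, 200]
  quality_noise_rms_mv: 0.05     # high-pass (40 Hz) residual RMS threshold

night:
  start_s: 0                     # midnight, seconds since midnight
  end_s: 32400                   # 9 AM
  minutes: 540

segments:
  excerpt_s: 300                 # 5-minute excerpts
  beats_per_sequence: 200        # implies HR > 40 bpm
  min_event_s: 300               # glucose events shorter than 5 min are dropped

voting:
  window_s: 600                  # 10-minute majority-vote windows
  certainty_threshold: 0.7       # dark vs light certainty on mean probability

saliency:
  histogram_threshold: 0.9       # counted positions exceed 0.9 in normalised maps

balancing:
  trigger_low_fraction: 0.25     # downsample normals when low < 25% of normal
  validation_fraction: 0.20
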
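alpha_pointwise: 0.05
bad_channel_z: 4.0
bands:
- - theta
  - 4.0
  - 8.0
- - alpha
  - 9.0
  - 14.0
- - beta
  - 15.0
  - 30.0
- - low_gamma
  - 30.0
  - 70.0
- - high_gamma
  - 70.0
  - 150.0
baseline_ms:
- -500.0
- 0.0
contrast_alpha: 0.025
electrodes_per_roi: 2
epoch_ms:
- -1500.0
- 3000.0
fs: 400.0
ica_fraction: 0.75
ica_n_drop: 2
n_items: 12
n_other_electrodes: 30
n_participants: 8
n_perm: 10000
n_repetitions: 5
n_sessions: 1
norms_categories: 4
norms_concepts: 12
norms_features: 48
notch_freqs:
- 60.0
- 120.0
- 180.0
phase_coded: false
rois:
- MTG
- ITG
- TP
- Fus
- PRC
run_ica: false
run_notch: true
run_phase: true
saccade_band:
- 20.0
- 190.0
seed: 0
snr: 10.0
t_range_ms:
- -100.0
- 1000.0
target_roi: PRC
test_window_ms:
- 200.0
- 400.0
tfr_cycles:
- 5.0
- 15.0
tfr_hi_hz: 190.0
tfr_lo_hz: 4.0
tfr_n_freqs: 60
tfr_times_ms:
- 200.0
- 220.0
- 240.0
- 260.0
- 280.0
- 300.0
- 320.0
- 340.0
- 360.0
- 380.0
- 400.0
window_half_ms: 50.0
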
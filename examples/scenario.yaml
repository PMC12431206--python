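# Example end-to-end scenario: one seated subject at 1 m broadside,
# two static clutter reflectors, 60 s record at a 20 Hz frame rate.
duration_s: 60.0
seed: 11

vital:
  ar_mm: 4.0          # respiration amplitude
  ti_s: 1.6           # inhalation duration
  te_s: 2.4           # exhalation duration
  tau_s: 0.8          # exhalation time constant
  kp_mm: 0.04         # atrial displacement
  kqrs_mm: 0.12       # ventricular displacement
  mean_ibi_s: 0.85
  ibi_jitter_sd_s: 0.03

radar:
  fc: 60.0e9
  bandwidth: 1.0e9
  n_samples: 64
  n_chirps: 8
  frame_rate: 20.0
  n_beam: 64

scene:
  target_position: [0.0, 1.0, 0.0]
  target_amplitude: 1.0
  # keep static reflectors a few range bins (c/2B = 0.15 m) away from the
  # subject: in-bin clutter adds a DC offset that distorts the phase
  clutter:
    - [[-0.5, 2.2, 0.1], 2.0]
    - [[0.4, 1.8, 0.0], 1.5]
  snr_db: 20.0

noise:
  snr_db: 10.0        # micro-motion noise, relative to heartbeat RMS

separation:
  gamma: 10.0
  max_iter: 30

eta: 0.5
dbscan_eps: 2.0
dbscan_min_samples: 4
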
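# Demo scenario: one straight dendrite, three inhibitory synapses 2-4 μm
# apart, twenty receptor-QD complexes recorded for 1200 frames at 20 Hz
# with trapping at synapses, QD blinking and 40 nm localization noise.
seed: 20240101

geometry:
  length: 12.0        # μm
  half_width: 1.0     # μm

synapses:
  n_inhibitory: 3
  n_excitatory: 0
  spacing: [2.0, 4.0]   # μm, consecutive centre distances
  punctum_radius: 0.2   # μm

simulation:
  n_receptors: 20
  D_long: 0.08          # μm²/s
  D_trans: 0.02         # μm²/s
  dt: 0.05              # s
  n_frames: 1200
  loc_noise_sd: 0.040   # μm
  trap_D_factor: 0.25
  trap_escape_prob: 0.02
  blink_on_prob: 0.4
  blink_off_prob: 0.1

linking:
  max_disp_px: 4.0
  max_gap: 25

analysis:
  msd_fit_points: 4
  mobile_threshold: 0.0075

anisotropy:
  convention: standard
  use_geometry: true

fpt:
  n_sim: 2000
  enabled: true
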
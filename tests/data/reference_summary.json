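{
  "D_long_um2s": {
    "median": 0.10684,
    "n": 26,
    "q25": 0.100281,
    "q75": 0.11113,
    "unit": "um2/s"
  },
  "D_long_vs_trans": {
    "n": 26,
    "p_value": 0.0,
    "statistic": 0.0,
    "test": "wilcoxon_paired"
  },
  "D_msd_um2s": {
    "median": 0.047983,
    "n": 26,
    "q25": 0.042604,
    "q75": 0.050952,
    "unit": "um2/s"
  },
  "D_trans_um2s": {
    "median": 0.050133,
    "n": 26,
    "q25": 0.047425,
    "q75": 0.05249,
    "unit": "um2/s"
  },
  "config": {
    "analysis": {
      "mobile_threshold": 0.0075,
      "msd_fit_points": 4,
      "paper_convention": false
    },
    "anisotropy": {
      "convention": "standard",
      "linearity_threshold": 0.8,
      "min_steps": 30,
      "use_geometry": true
    },
    "fpt": {
      "enabled": true,
      "n_sim": 2000
    },
    "geometry": {
      "half_width": 1.0,
      "length": 12.0
    },
    "inputs": {
      "synapses_csv": null,
      "trajectories_csv": null
    },
    "linking": {
      "max_disp_px": 4.0,
      "max_gap": 25
    },
    "seed": 20240101,
    "simulation": {
      "D_long": 0.08,
      "D_trans": 0.02,
      "blink_off_prob": 0.1,
      "blink_on_prob": 0.4,
      "drift_long": 0.0,
      "drift_trans": 0.0,
      "dt": 0.05,
      "loc_noise_sd": 0.04,
      "n_frames": 1200,
      "n_receptors": 20,
      "trap_D_factor": 0.25,
      "trap_escape_prob": 0.02
    },
    "synapses": {
      "n_excitatory": 0,
      "n_inhibitory": 3,
      "punctum_radius": 0.2,
      "spacing": [
        2.0,
        4.0
      ]
    }
  },
  "dwell_time_s": {
    "median": 0.15,
    "n": 303,
    "q25": 0.05,
    "q75": 0.4,
    "unit": "s"
  },
  "fpt_intercept_pct": {
    "median": 0.0,
    "n": 7,
    "q25": 0.0,
    "q75": 2.05,
    "unit": "%"
  },
  "intersynaptic_fraction_of_synaptic": 0.235294,
  "mobile_fraction": 1.0,
  "n_analyzed_tracks": 26,
  "n_dwell_episodes": 303,
  "n_localizations": 18972,
  "n_synaptic_tracks": 17,
  "n_tracks": 27,
  "n_transitions": 7,
  "transition_time_s": {
    "median": 7.2,
    "n": 7,
    "q25": 3.25,
    "q75": 11.275,
    "unit": "s"
  }
}
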
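{
  "smooth_pursuit": {
    "description": "Smooth-pursuit program as executed on the rotation stage (20 deg legs in 1.5 s with 1 s holds).",
    "profile": "triangular",
    "sample_rate_hz": 2000,
    "segments": [
      {"delta_deg": 20.0, "duration_s": 1.5, "pause_s": 1.0},
      {"delta_deg": 20.0, "duration_s": 1.5, "pause_s": 1.0},
      {"delta_deg": -20.0, "duration_s": 1.5, "pause_s": 1.0},
      {"delta_deg": 20.0, "duration_s": 1.5, "pause_s": 0.0}
    ]
  },
  "scene_saccades": {
    "description": "Scene-perception saccade program: three 4 deg saccades in 50 ms with 330 ms fixations, then a 12 deg return in 1 s.",
    "profile": "triangular",
    "sample_rate_hz": 2000,
    "segments": [
      {"delta_deg": 4.0, "duration_s": 0.05, "pause_s": 0.33},
      {"delta_deg": 4.0, "duration_s": 0.05, "pause_s": 0.33},
      {"delta_deg": 4.0, "duration_s": 0.05, "pause_s": 0.33},
      {"delta_deg": -12.0, "duration_s": 1.0, "pause_s": 0.0}
    ]
  },
  "micro_saccades": {
    "description": "Fixational micro-saccade program: 0.55 deg jumps in 14 ms repeating every 1.25 s, interleaved with 10-20 deg repositioning moves in 500 ms.",
    "profile": "triangular",
    "sample_rate_hz": 2000,
    "segments": [
      {"delta_deg": 0.55, "duration_s": 0.014, "pause_s": 1.25},
      {"delta_deg": -0.55, "duration_s": 0.014, "pause_s": 1.25},
      {"delta_deg": 10.0, "duration_s": 0.5, "pause_s": 1.25},
      {"delta_deg": 0.55, "duration_s": 0.014, "pause_s": 1.25},
      {"delta_deg": -0.55, "duration_s": 0.014, "pause_s": 1.25},
      {"delta_deg": -20.0, "duration_s": 0.5, "pause_s": 0.0},
      {"delta_deg": -0.55, "duration_s": 0.014, "pause_s": 1.25},
      {"delta_deg": -0.55, "duration_s": 0.014, "pause_s": 1.25},
      {"delta_deg": 10.0, "duration_s": 0.5, "pause_s": 1.25}
    ]
  },
  "smooth_pursuit_programmed": {
    "description": "Smooth pursuit as originally programmed: 20 deg in 1.8 s (triangular peak ~22 deg/s), 50 ms stops, mirrored return.",
    "profile": "triangular",
    "sample_rate_hz": 2000,
    "segments": [
      {"delta_deg": 20.0, "duration_s": 1.8, "pause_s": 0.05},
      {"delta_deg": -20.0, "duration_s": 1.8, "pause_s": 0.05},
      {"delta_deg": -20.0, "duration_s": 1.8, "pause_s": 0.05},
      {"delta_deg": 20.0, "duration_s": 1.8, "pause_s": 0.0}
    ]
  },
  "scene_saccades_programmed": {
    "description": "Reading-style saccades as originally programmed: 2 deg in 100 ms every 330 ms up to 8 deg, return in 400 ms.",
    "profile": "triangular",
    "sample_rate_hz": 2000,
    "segments": [
      {"delta_deg": 2.0, "duration_s": 0.1, "pause_s": 0.33},
      {"delta_deg": 2.0, "duration_s": 0.1, "pause_s": 0.33},
      {"delta_deg": 2.0, "duration_s": 0.1, "pause_s": 0.33},
      {"delta_deg": 2.0, "duration_s": 0.1, "pause_s": 0.33},
      {"delta_deg": -8.0, "duration_s": 0.4, "pause_s": 0.0}
    ]
  },
  "micro_saccades_programmed": {
    "description": "Micro-saccades as originally programmed: 0.4 deg back and forth in 20 ms every 1.25 s.",
    "profile": "triangular",
    "sample_rate_hz": 2000,
    "segments": [
      {"delta_deg": 0.4, "duration_s": 0.02, "pause_s": 1.25},
      {"delta_deg": -0.4, "duration_s": 0.02, "pause_s": 1.25}
    ]
  }
}
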
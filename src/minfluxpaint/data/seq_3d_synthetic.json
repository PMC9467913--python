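{
  "ndim": 3,
  "description": "Synthetic stand-in for a 3D MINFLUX iteration sequence: one prelocalization followed by nine iterations ending at L = 40 nm. Only the iteration count and the final L follow the instrument convention; the intermediate parameters are plausible placeholders, not instrument values.",
  "iterations": [
    {"name": "prelocalization", "L": 160, "photon_limit": null, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 1},
    {"name": "iteration_1", "L": 302, "photon_limit": 150, "dwell_ms": 1.0, "cfr_limit": 0.5, "power_factor": 1},
    {"name": "iteration_2", "L": 239, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 1},
    {"name": "iteration_3", "L": 189, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 2},
    {"name": "iteration_4", "L": 149, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": 0.8, "power_factor": 2},
    {"name": "iteration_5", "L": 118, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 3},
    {"name": "iteration_6", "L": 93, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 4},
    {"name": "iteration_7", "L": 74, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 4},
    {"name": "iteration_8", "L": 58, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 5},
    {"name": "iteration_9", "L": 40, "photon_limit": 150, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 6}
  ]
}
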
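{
  "ndim": 2,
  "description": "Default 2D MINFLUX iteration sequence: one prelocalization followed by four iterations with shrinking TCP diameter L.",
  "iterations": [
    {"name": "prelocalization", "L": 160, "photon_limit": null, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 1},
    {"name": "iteration_1", "L": 288, "photon_limit": 150, "dwell_ms": 1.0, "cfr_limit": 0.5, "power_factor": 1},
    {"name": "iteration_2", "L": 151, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 2},
    {"name": "iteration_3", "L": 76, "photon_limit": 100, "dwell_ms": 1.0, "cfr_limit": 0.8, "power_factor": 4},
    {"name": "iteration_4", "L": 40, "photon_limit": 150, "dwell_ms": 1.0, "cfr_limit": "off", "power_factor": 6}
  ]
}
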
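{
 "spec": {
  "sources": [
   "lFEF",
   "rFEF",
   "lIPS",
   "rIPS",
   "rTPJ"
  ],
  "forward_edges": [
   [
    "rTPJ",
    "lFEF"
   ],
   [
    "rTPJ",
    "rFEF"
   ],
   [
    "lIPS",
    "lFEF"
   ],
   [
    "rIPS",
    "rFEF"
   ]
  ],
  "backward_edges": [
   [
    "lFEF",
    "rTPJ"
   ],
   [
    "rFEF",
    "rTPJ"
   ],
   [
    "lFEF",
    "lIPS"
   ],
   [
    "rFEF",
    "rIPS"
   ]
  ],
  "input_targets": [
   "rTPJ",
   "lIPS",
   "rIPS"
  ],
  "modulated_edges": [
   [
    "rTPJ",
    "lFEF"
   ],
   [
    "rTPJ",
    "rFEF"
   ],
   [
    "lFEF",
    "rTPJ"
   ],
   [
    "rFEF",
    "rTPJ"
   ]
  ],
  "design": [
   0.0,
   1.0
  ],
  "condition_labels": [
   "early",
   "late"
  ]
 },
 "params": {
  "a_fwd": [
   0.0,
   0.0,
   0.0,
   0.0
  ],
  "a_bwd": [
   0.0,
   0.0,
   0.0,
   0.0
  ],
  "b": [
   0.0,
   0.1,
   -0.4,
   -0.4
  ],
  "g": [
   0.0,
   0.0,
   0.0
  ],
  "c": [
   0.0,
   0.0,
   0.0
  ],
  "kappa": [
   0.0,
   0.0,
   0.0,
   0.0
  ],
  "input_onset": 0.06,
  "input_dispersion": 0.016,
  "input_amplitude": 1.0,
  "lead_gain": [
   [
    1.0,
    0.5,
    -0.3,
    0.2,
    0.4
   ],
   [
    -0.4,
    1.0,
    0.2,
    -0.3,
    0.5
   ],
   [
    0.3,
    -0.2,
    1.0,
    0.5,
    -0.4
   ],
   [
    0.2,
    0.3,
    -0.5,
    1.0,
    0.6
   ]
  ],
  "log_noise_precision": 4.0,
  "n_channels": 4
 },
 "design": [
  0.0,
  1.0
 ],
 "snr_db": 10.0,
 "seed": 101
}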
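{
  "comment": "Default representation-profile template table. Each developmental-process category has a canonical significance/direction signature over the pairwise comparisons (T1vT2, T2vT3, T1vT3), optional extra patterns mapped to it explicitly, and a mean log-abundance trajectory (multiples of log effect size at T1, T2, T3) used by the synthetic-data generator. Profile shapes are a documented in-package reconstruction, user-editable; the housekeeping category is reserved for proteins with no significant comparison. Triples not listed are resolved to the Hamming-nearest signature, ties broken by the priority order.",
  "states": ["up", "down", "ns"],
  "comparisons": ["T1vT2", "T2vT3", "T1vT3"],
  "priority": [
    "molting",
    "secondary_cement_production_I",
    "secondary_cement_production_II",
    "cement_maintenance",
    "feeding",
    "feeding_and_oogenesis",
    "detachment"
  ],
  "categories": {
    "housekeeping": {
      "signature": ["ns", "ns", "ns"],
      "trajectory": [0, 0, 0]
    },
    "molting": {
      "signature": ["down", "ns", "down"],
      "extra_patterns": [["down", "down", "down"]],
      "trajectory": [1, 0, 0]
    },
    "secondary_cement_production_I": {
      "signature": ["up", "down", "ns"],
      "extra_patterns": [["up", "down", "down"], ["up", "down", "up"]],
      "trajectory": [0, 1, 0]
    },
    "secondary_cement_production_II": {
      "signature": ["up", "ns", "up"],
      "trajectory": [0, 1, 1]
    },
    "cement_maintenance": {
      "signature": ["ns", "down", "down"],
      "trajectory": [1, 1, 0]
    },
    "feeding": {
      "signature": ["up", "up", "up"],
      "trajectory": [0, 0.5, 1]
    },
    "feeding_and_oogenesis": {
      "signature": ["ns", "up", "up"],
      "extra_patterns": [["ns", "ns", "up"]],
      "trajectory": [0, 0, 1]
    },
    "detachment": {
      "signature": ["down", "up", "ns"],
      "trajectory": [1, 0, 1]
    }
  }
}
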
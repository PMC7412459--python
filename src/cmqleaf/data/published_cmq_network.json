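{
  "description": "Published 2-3-3 tanh network predicting CMQ (qL*, qa*, qb*) from SR-S and Lb-A, coefficients at printed 4-decimal precision",
  "pre_activation_scale": 0.5,
  "hidden": [
    {"name": "H1", "bias": -1.0617, "srs": 0.0311, "lba": 0.6420},
    {"name": "H2", "bias": 1.4045, "srs": -0.5334, "lba": -0.0241},
    {"name": "H3", "bias": -0.1777, "srs": 0.3507, "lba": 0.9401}
  ],
  "output": [
    {"name": "qL", "bias": 76.8278, "weights": [-23.3637, 0.6636, -24.9085]},
    {"name": "qa", "bias": -13.0326, "weights": [24.3295, 34.7418, 22.0398]},
    {"name": "qb", "bias": 28.5284, "weights": [-34.0210, -5.4716, 0.7791]}
  ]
}
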
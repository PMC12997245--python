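{
  "descriptor_names": [
    "C-0.008", "C-0.004", "C-0.003", "C0.002", "C0.003", "C0.005",
    "C0.009", "C0.014", "A-0.006", "A-0.001", "A0.004"
  ],
  "coefficients": {
    "C-0.008": 0.0557,
    "C-0.004": -0.1161,
    "C-0.003": 0.1529,
    "C0.002": 0.1482,
    "C0.003": -0.3281,
    "C0.005": 0.1583,
    "C0.009": -0.3812,
    "C0.014": -0.3416,
    "A-0.006": -0.0536,
    "A-0.001": 0.0159,
    "A0.004": -0.0114
  },
  "intercept": -2.6595,
  "meta": {
    "source": "published 11-descriptor MLR-QSAR model for Log 1/EC50 (AChE, log uM)",
    "training_size": 183,
    "coefficient_precision": "4 decimal places as printed"
  }
}
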
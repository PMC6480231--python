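{
  "version": "1.0",
  "description": "Published logistic-regression coefficients (alpha, beta, p) for the four level boundaries and the derived discomfort thresholds per indicator. Units: I1, I2 in micrometres; I3 in micrometres per second.",
  "logistic_fits": {
    "I1": {
      "T1": {"alpha": 5.504, "beta": 0.118, "p_value": 0.002},
      "T2": {"alpha": 3.092, "beta": 0.039, "p_value": 0.001},
      "T3": {"alpha": 34.5, "beta": 0.254, "p_value": 0.000},
      "T4": {"alpha": 4.637, "beta": 0.056, "p_value": 0.000}
    },
    "I2": {
      "T1": {"alpha": 5.553, "beta": 0.313, "p_value": 0.004},
      "T2": {"alpha": 2.433, "beta": 0.075, "p_value": 0.001},
      "T3": {"alpha": 24.385, "beta": 0.315, "p_value": 0.001},
      "T4": {"alpha": 3.710, "beta": 0.110, "p_value": 0.000}
    },
    "I3": {
      "T1": {"alpha": 2.017, "beta": 0.345, "p_value": 0.025},
      "T2": {"alpha": 4.938, "beta": 0.550, "p_value": 0.000},
      "T3": {"alpha": 2.190, "beta": 0.107, "p_value": 0.000},
      "T4": {"alpha": 6.311, "beta": 0.693, "p_value": 0.000}
    }
  },
  "thresholds": {
    "I1": {"t1": 46.61, "t2": 78.87, "t3": 139.87, "t4": 82.74, "tc": 80.81},
    "I2": {"t1": 17.76, "t2": 32.31, "t3": 77.51, "t4": 33.63, "tc": 32.97},
    "I3": {"t1": 5.84, "t2": 8.98, "t3": 20.45, "t4": 9.10, "tc": 9.04}
  }
}
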
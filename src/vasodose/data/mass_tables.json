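{
  "male": {
    "sex_label": "adult male",
    "mL": 2360.00,
    "mLB": 560.48,
    "mLP": 1799.52,
    "mLBM": 176.70,
    "mLCTM": 2183.28,
    "mLBmu": 383.77
  },
  "female": {
    "sex_label": "adult female",
    "mL": 1809.99,
    "mLB": 425.26,
    "mLP": 1384.73,
    "mLBM": 129.96,
    "mLCTM": 1679.99,
    "mLBmu": 295.31
  }
}
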
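{
  "percent": true,
  "elements": ["H", "C", "N", "O", "Na", "P", "S", "Cl", "K", "Fe"],
  "compositions": {
    "liver": {
      "fractions": {"H": 10.20, "C": 13.20, "N": 3.10, "O": 72.30, "Na": 0.20, "P": 0.20, "S": 0.30, "Cl": 0.20, "K": 0.30, "Fe": 0.00},
      "density": 1.060
    },
    "blood": {
      "fractions": {"H": 10.20, "C": 11.00, "N": 3.30, "O": 74.50, "Na": 0.10, "P": 0.10, "S": 0.20, "Cl": 0.30, "K": 0.20, "Fe": 0.10},
      "density": 1.060
    },
    "parenchyma_derived": {
      "fractions": {"H": 10.20, "C": 13.38, "N": 3.08, "O": 72.12, "Na": 0.21, "P": 0.21, "S": 0.31, "Cl": 0.19, "K": 0.31, "Fe": 0.00},
      "density": 1.060
    },
    "plasma_lymph": {
      "fractions": {"H": 10.80, "C": 4.10, "N": 1.10, "O": 83.20, "Na": 0.30, "P": 0.00, "S": 0.10, "Cl": 0.40, "K": 0.00, "Fe": 0.00},
      "density": 1.000
    },
    "cell": {
      "fractions": {"H": 10.14, "C": 14.42, "N": 3.25, "O": 70.92, "Na": 0.21, "P": 0.24, "S": 0.34, "Cl": 0.16, "K": 0.34, "Fe": 0.00},
      "density": 1.068
    }
  }
}
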
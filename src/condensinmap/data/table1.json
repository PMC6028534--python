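{
  "description": "Chromosome-bound Condensin subunit totals per HeLa Kyoto cell (molecules, mean +/- SD) and total chromatid-axis length (um) for three mitotic phases, measured by FCS-calibrated live-cell imaging and Airyscan axis tracing.",
  "genome": {
    "genome_size_bp": 7.9e9,
    "n_chromosomes": 64,
    "replicated": true
  },
  "phases": {
    "prometaphase": {
      "total_axis_length_um": 1311.7,
      "total_axis_length_um_sd": 245.2,
      "totals": {
        "SMC4": 247952,
        "CAP-D2": 152558,
        "CAP-H": 145478,
        "CAP-D3": 73267,
        "CAP-H2": 36451
      },
      "totals_sd": {
        "SMC4": 43519,
        "CAP-D2": 20965,
        "CAP-H": 27626,
        "CAP-D3": 14861,
        "CAP-H2": 13604
      }
    },
    "metaphase": {
      "total_axis_length_um": 1162.5,
      "total_axis_length_um_sd": 190.4,
      "totals": {
        "SMC4": 252652,
        "CAP-D2": 153519,
        "CAP-H": 140965,
        "CAP-D3": 71408,
        "CAP-H2": 34543
      },
      "totals_sd": {
        "SMC4": 39130,
        "CAP-D2": 22952,
        "CAP-H": 26521,
        "CAP-D3": 14999,
        "CAP-H2": 12521
      }
    },
    "anaphase": {
      "total_axis_length_um": 923.1,
      "total_axis_length_um_sd": 120.7,
      "totals": {
        "SMC4": 325522,
        "CAP-D2": 216857,
        "CAP-H": 194427,
        "CAP-D3": 71244,
        "CAP-H2": 34677
      },
      "totals_sd": {
        "SMC4": 48878,
        "CAP-D2": 32900,
        "CAP-H": 37121,
        "CAP-D3": 16174,
        "CAP-H2": 13294
      }
    }
  }
}
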
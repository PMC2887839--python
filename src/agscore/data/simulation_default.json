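{
  "description": "Default cohort simulation: per-dose-group genotype frequencies (percent, ordered by genotype score 0/1/2), observed group sizes, and phenotype distributions of the source cohort.",
  "notes": [
    "rs9923231 high-dose GG entry printed as 35.0 sums the row to 85.0; it is restored here to 50.0 (= 100 - 5.6 - 44.4).",
    "Rows summing to 99.9 or 100.1 from rounding are renormalised to 1 at load time by dividing by the row sum.",
    "Markers are sampled independently within a subject; real within-gene LD between the VKORC1 SNPs is not reproduced."
  ],
  "group_sizes": {"low": 34, "medium": 141, "high": 18},
  "genotype_freqs_percent": {
    "low": {
      "CYP2C9*2": [0.0, 32.4, 67.6],
      "CYP2C9*3": [14.7, 29.4, 55.9],
      "VKORC1_-1639G>A": [38.2, 35.3, 26.5],
      "VKORC1_497T>G": [15.2, 39.4, 45.5],
      "VKORC1_1173C>T": [23.5, 35.3, 41.2]
    },
    "medium": {
      "CYP2C9*2": [2.8, 33.3, 63.8],
      "CYP2C9*3": [1.4, 15.6, 83.0],
      "VKORC1_-1639G>A": [21.3, 44.7, 34.0],
      "VKORC1_497T>G": [10.0, 39.3, 50.7],
      "VKORC1_1173C>T": [14.2, 46.8, 39.0]
    },
    "high": {
      "CYP2C9*2": [5.6, 11.1, 83.3],
      "CYP2C9*3": [0.0, 0.0, 100.0],
      "VKORC1_-1639G>A": [5.6, 44.4, 50.0],
      "VKORC1_497T>G": [5.9, 29.4, 64.7],
      "VKORC1_1173C>T": [5.6, 44.4, 50.0]
    }
  },
  "dose_ranges": {"low": [0.0, 7.0], "medium": [7.0, 28.0], "high": [28.0, 56.0]},
  "sex_male_fraction": 0.518,
  "age_mean": 64.0,
  "age_sd": 13.9,
  "comedication_prevalences": {},
  "seed": 20100618
}
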
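{
  "description": "Default five-marker CYP2C9/VKORC1 panel with genotype->score assignments (0 = very slow metaboliser / lowest dose, 1 = slow / medium, 2 = normal / highest dose).",
  "panel": [
    {
      "key": "CYP2C9*2",
      "rsid": "rs1799853",
      "gene": "CYP2C9",
      "alleles": ["C", "T"],
      "scores": {"TT": 0, "CT": 1, "CC": 2}
    },
    {
      "key": "CYP2C9*3",
      "rsid": "rs1057910",
      "gene": "CYP2C9",
      "alleles": ["A", "C"],
      "scores": {"CC": 0, "AC": 1, "AA": 2}
    },
    {
      "key": "VKORC1_-1639G>A",
      "rsid": "rs9923231",
      "gene": "VKORC1",
      "alleles": ["A", "G"],
      "scores": {"AA": 0, "AG": 1, "GG": 2}
    },
    {
      "key": "VKORC1_497T>G",
      "rsid": "rs2884737",
      "gene": "VKORC1",
      "alleles": ["G", "T"],
      "scores": {"GG": 0, "GT": 1, "TT": 2}
    },
    {
      "key": "VKORC1_1173C>T",
      "rsid": "rs9934438",
      "gene": "VKORC1",
      "alleles": ["C", "T"],
      "scores": {"TT": 0, "CT": 1, "CC": 2}
    }
  ]
}
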
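{
  "comment": "Element-keyed Lennard-Jones parameters: rmin/2 in Angstrom, epsilon in kcal/mol. Literature-typical values; swappable via LJParams(table_path=...).",
  "elements": {
    "H":  {"rmin_half": 1.20, "epsilon": 0.025},
    "C":  {"rmin_half": 2.00, "epsilon": 0.070},
    "N":  {"rmin_half": 1.85, "epsilon": 0.200},
    "O":  {"rmin_half": 1.70, "epsilon": 0.120},
    "S":  {"rmin_half": 2.00, "epsilon": 0.450},
    "Br": {"rmin_half": 1.98, "epsilon": 0.320},
    "Cu": {"rmin_half": 1.40, "epsilon": 0.050},
    "Gd": {"rmin_half": 1.76, "epsilon": 0.200}
  }
}
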
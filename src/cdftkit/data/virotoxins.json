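{
  "description": "Frontier-orbital energies, published global descriptors, pKa predictions and extreme-site local descriptors for the five virotoxin peptides (eV, nm; dual values pre-scaled by 100).",
  "molecules": ["Alaviroidin", "Deoxoviroidin", "Deoxoviroisin", "Viroidin", "Viroisin"],
  "frontier": {
    "Alaviroidin":   {"epsilon_homo": -6.072, "epsilon_lumo": -1.700},
    "Deoxoviroidin": {"epsilon_homo": -5.929, "epsilon_lumo": -1.467},
    "Deoxoviroisin": {"epsilon_homo": -5.681, "epsilon_lumo": -1.228},
    "Viroidin":      {"epsilon_homo": -6.056, "epsilon_lumo": -1.622},
    "Viroisin":      {"epsilon_homo": -5.888, "epsilon_lumo": -1.593}
  },
  "expected_global": {
    "Alaviroidin":   {"gap": 4.372, "lambda_max_nm": 284, "electronegativity": 3.886, "global_hardness": 4.372, "electrophilicity": 1.727, "electrodonating_power": 5.670, "electroaccepting_power": 1.784, "net_electrophilicity": 7.454},
    "Deoxoviroidin": {"gap": 4.462, "lambda_max_nm": 278, "electronegativity": 3.698, "global_hardness": 4.462, "electrophilicity": 1.533, "electrodonating_power": 5.193, "electroaccepting_power": 1.495, "net_electrophilicity": 6.688},
    "Deoxoviroisin": {"gap": 4.453, "lambda_max_nm": 278, "electronegativity": 3.454, "global_hardness": 4.453, "electrophilicity": 1.340, "electrodonating_power": 4.685, "electroaccepting_power": 1.231, "net_electrophilicity": 5.916},
    "Viroidin":      {"gap": 4.434, "lambda_max_nm": 280, "electronegativity": 3.839, "global_hardness": 4.434, "electrophilicity": 1.662, "electrodonating_power": 5.520, "electroaccepting_power": 1.682, "net_electrophilicity": 7.202},
    "Viroisin":      {"gap": 4.295, "lambda_max_nm": 289, "electronegativity": 3.740, "global_hardness": 4.295, "electrophilicity": 1.629, "electrodonating_power": 5.396, "electroaccepting_power": 1.655, "net_electrophilicity": 7.051}
  },
  "expected_pka": {
    "Alaviroidin":   {"published_label": "FAR", "pka": 12.69},
    "Deoxoviroidin": {"published_label": "FAY", "pka": 12.62},
    "Deoxoviroisin": {"published_label": "FVY", "pka": 12.63},
    "Viroidin":      {"published_label": "FWC", "pka": 12.64},
    "Viroisin":      {"published_label": "FWY", "pka": 12.76}
  },
  "pka_label_note": "Published pKa row labels do not carry the molecule names; the mapping above follows descriptor-table row order and is confirmed because each published pKa equals 16.3088 - 0.8268*eta of the corresponding row at 2 d.p.",
  "extreme_sites": {
    "Alaviroidin": [
      {"atom_index": 50, "element": "C", "dual_scaled": 8.71,  "parr_plus": 0.227, "parr_minus": 0.007},
      {"atom_index": 24, "element": "N", "dual_scaled": -13.59, "parr_plus": 0.048, "parr_minus": 0.275}
    ],
    "Deoxoviroidin": [
      {"atom_index": 1,  "element": "S", "dual_scaled": 6.43,  "parr_plus": 0.071, "parr_minus": 0.010},
      {"atom_index": 48, "element": "C", "dual_scaled": -11.44, "parr_plus": 0.103, "parr_minus": 0.358}
    ],
    "Deoxoviroisin": [
      {"atom_index": 59, "element": "C", "dual_scaled": 12.91,  "parr_plus": 0.259, "parr_minus": 0.067},
      {"atom_index": 49, "element": "C", "dual_scaled": -15.01, "parr_plus": 0.058, "parr_minus": 0.386}
    ],
    "Viroidin": [
      {"atom_index": 50, "element": "C", "dual_scaled": 7.07,  "parr_plus": 0.268, "parr_minus": 0.045},
      {"atom_index": 24, "element": "N", "dual_scaled": -10.04, "parr_plus": 0.050, "parr_minus": 0.225}
    ],
    "Viroisin": [
      {"atom_index": 1,  "element": "S", "dual_scaled": 7.83,  "parr_plus": 0.086, "parr_minus": 0.005},
      {"atom_index": 25, "element": "N", "dual_scaled": -9.77, "parr_plus": 0.044, "parr_minus": 0.206}
    ]
  }
}
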
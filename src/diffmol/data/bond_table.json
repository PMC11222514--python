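{
  "version": 1,
  "units": "pm",
  "comment": "Covalent reference bond lengths per (element pair, bond order) with per-order distance margins, and permitted total valences per element (keyed by formal charge). Convention of the distance-based bond inference used for atom/molecule stability scoring of 3D generative models.",
  "lengths": {
    "1": {
      "H-H": 74, "H-C": 109, "H-N": 101, "H-O": 96, "H-F": 92, "H-B": 119,
      "H-Si": 148, "H-P": 144, "H-As": 152, "H-S": 134, "H-Cl": 127,
      "H-Br": 141, "H-I": 161,
      "C-C": 154, "C-N": 147, "C-O": 143, "C-F": 135, "C-Si": 185,
      "C-P": 184, "C-S": 182, "C-Cl": 177, "C-Br": 194, "C-I": 214,
      "N-N": 145, "N-O": 140, "N-F": 136, "N-Cl": 175, "N-Br": 214,
      "N-S": 168, "N-I": 222, "N-P": 177,
      "O-O": 148, "O-F": 142, "O-Br": 172, "O-S": 151, "O-P": 163,
      "O-Si": 163, "O-Cl": 164, "O-I": 194,
      "F-F": 142, "F-S": 158, "F-Si": 160, "F-Cl": 166, "F-Br": 178,
      "F-P": 156, "F-I": 187,
      "B-Cl": 175,
      "Si-Si": 233, "Si-Cl": 202, "Si-S": 200, "Si-Br": 215, "Si-I": 243,
      "Cl-Cl": 199, "Cl-P": 203, "Cl-S": 207, "Cl-Br": 214,
      "S-S": 204, "S-P": 210, "S-Br": 225, "S-I": 234,
      "Br-Br": 228, "Br-P": 222,
      "P-P": 221,
      "I-I": 266
    },
    "2": {
      "C-C": 134, "C-N": 129, "C-O": 120, "C-S": 160,
      "N-N": 125, "N-O": 121,
      "O-O": 121, "O-P": 150,
      "P-S": 186
    },
    "3": {
      "C-C": 120, "C-N": 116, "C-O": 113,
      "N-N": 110
    }
  },
  "margins": {"1": 10, "2": 5, "3": 3},
  "allowed_valences": {
    "H": {"0": [1]},
    "C": {"0": [4], "1": [3], "-1": [3]},
    "N": {"0": [3], "1": [4], "-1": [2]},
    "O": {"0": [2], "1": [3], "-1": [1]},
    "F": {"0": [1]},
    "B": {"0": [3]},
    "Al": {"0": [3]},
    "Si": {"0": [4]},
    "P": {"0": [3, 5]},
    "S": {"0": [4]},
    "Cl": {"0": [1]},
    "As": {"0": [3]},
    "Br": {"0": [1]},
    "I": {"0": [1]},
    "Hg": {"0": [1, 2]},
    "Bi": {"0": [3, 5]}
  }
}
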
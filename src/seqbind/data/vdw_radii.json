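{
  "H": 1.20,
  "C": 1.70,
  "N": 1.55,
  "O": 1.52,
  "F": 1.47,
  "P": 1.80,
  "S": 1.80,
  "CL": 1.75,
  "BR": 1.85,
  "I": 1.98,
  "SE": 1.90,
  "B": 1.92,
  "SI": 2.10,
  "LI": 1.82,
  "NA": 2.27,
  "K": 2.75,
  "RB": 3.03,
  "CS": 3.43,
  "MG": 1.73,
  "CA": 2.40,
  "SR": 2.49,
  "BA": 2.68,
  "MN": 2.05,
  "FE": 2.05,
  "CO": 2.00,
  "NI": 1.63,
  "CU": 1.40,
  "ZN": 1.39,
  "CD": 1.58,
  "HG": 1.55,
  "AL": 1.84,
  "MO": 2.10,
  "W": 2.10,
  "V": 2.05
}
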
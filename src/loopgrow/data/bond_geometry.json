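{
  "comment": "Standard backbone covalent geometry (Engh-Huber-style stand-in values; the exact source-table values are not reproduced here). Lengths in Angstrom, angles in degrees. Version 1.",
  "version": 1,
  "bonds": {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.530
  },
  "angles": {
    "C-N-CA": 121.7,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "CA-C-O": 120.8,
    "O-C-N": 123.0,
    "N-CA-CB": 110.5
  },
  "omega_trans": 180.0,
  "proline": {
    "C-N-CA": 122.6,
    "N-CA-C": 112.1
  },
  "glycine": {
    "N-CA-C": 112.5
  }
}
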
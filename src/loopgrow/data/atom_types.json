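{
  "comment": "Heavy-atom type scheme: 4 backbone types plus 16 side-chain types (6 carbon, 6 nitrogen, 3 oxygen, 1 sulfur classes). Editable; the grouping is a coarse Rosetta-like partition.",
  "backbone": {"N": "bbN", "CA": "bbCA", "C": "bbC", "O": "bbO", "OXT": "bbO"},
  "side_chain_classes": {
    "carbon": ["Cch3", "Cch2", "Cch1", "Caro", "Ccam", "Cgua"],
    "nitrogen": ["Namd", "Nhis", "Ntrp", "Nlys", "Narge", "Nargh"],
    "oxygen": ["Ohyd", "Oamd", "Ocarbox"],
    "sulfur": ["S"]
  },
  "side_chain": {
    "ALA": {"CB": "Cch3"},
    "ARG": {"CB": "Cch2", "CG": "Cch2", "CD": "Cch2", "NE": "Narge", "CZ": "Cgua", "NH1": "Nargh", "NH2": "Nargh"},
    "ASN": {"CB": "Cch2", "CG": "Ccam", "OD1": "Oamd", "ND2": "Namd"},
    "ASP": {"CB": "Cch2", "CG": "Ccam", "OD1": "Ocarbox", "OD2": "Ocarbox"},
    "CYS": {"CB": "Cch2", "SG": "S"},
    "GLN": {"CB": "Cch2", "CG": "Cch2", "CD": "Ccam", "OE1": "Oamd", "NE2": "Namd"},
    "GLU": {"CB": "Cch2", "CG": "Cch2", "CD": "Ccam", "OE1": "Ocarbox", "OE2": "Ocarbox"},
    "GLY": {},
    "HIS": {"CB": "Cch2", "CG": "Caro", "ND1": "Nhis", "CD2": "Caro", "CE1": "Caro", "NE2": "Nhis"},
    "ILE": {"CB": "Cch1", "CG1": "Cch2", "CG2": "Cch3", "CD1": "Cch3"},
    "LEU": {"CB": "Cch2", "CG": "Cch1", "CD1": "Cch3", "CD2": "Cch3"},
    "LYS": {"CB": "Cch2", "CG": "Cch2", "CD": "Cch2", "CE": "Cch2", "NZ": "Nlys"},
    "MET": {"CB": "Cch2", "CG": "Cch2", "SD": "S", "CE": "Cch3"},
    "PHE": {"CB": "Cch2", "CG": "Caro", "CD1": "Caro", "CD2": "Caro", "CE1": "Caro", "CE2": "Caro", "CZ": "Caro"},
    "PRO": {"CB": "Cch2", "CG": "Cch2", "CD": "Cch2"},
    "SER": {"CB": "Cch2", "OG": "Ohyd"},
    "THR": {"CB": "Cch1", "OG1": "Ohyd", "CG2": "Cch3"},
    "TRP": {"CB": "Cch2", "CG": "Caro", "CD1": "Caro", "CD2": "Caro", "NE1": "Ntrp", "CE2": "Caro", "CE3": "Caro", "CZ2": "Caro", "CZ3": "Caro", "CH2": "Caro"},
    "TYR": {"CB": "Cch2", "CG": "Caro", "CD1": "Caro", "CD2": "Caro", "CE1": "Caro", "CE2": "Caro", "CZ": "Caro", "OH": "Ohyd"},
    "VAL": {"CB": "Cch1", "CG1": "Cch3", "CG2": "Cch3"}
  },
  "vdw_radii": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
}
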
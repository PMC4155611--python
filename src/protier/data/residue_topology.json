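{
  "_format": "residue code -> {one: one-letter code, atoms: {PDB atom name: element}, bonds: [[name, name], ...]}. Heavy atoms only (hydrogen-suppressed), generic in-chain form (no OXT), aromatic bonds as single edges. Backbone N-CA-C-O common to all residues; PRO closes a ring through its backbone N.",
  "ALA": {
    "one": "A",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"]]
  },
  "ARG": {
    "one": "R",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD": "C", "NE": "N", "CZ": "C", "NH1": "N", "NH2": "N"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD"], ["CD", "NE"], ["NE", "CZ"], ["CZ", "NH1"], ["CZ", "NH2"]]
  },
  "ASN": {
    "one": "N",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "OD1": "O", "ND2": "N"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "OD1"], ["CG", "ND2"]]
  },
  "ASP": {
    "one": "D",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "OD1": "O", "OD2": "O"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "OD1"], ["CG", "OD2"]]
  },
  "CYS": {
    "one": "C",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "SG": "S"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "SG"]]
  },
  "GLN": {
    "one": "Q",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD": "C", "OE1": "O", "NE2": "N"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD"], ["CD", "OE1"], ["CD", "NE2"]]
  },
  "GLU": {
    "one": "E",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD": "C", "OE1": "O", "OE2": "O"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD"], ["CD", "OE1"], ["CD", "OE2"]]
  },
  "GLY": {
    "one": "G",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"]]
  },
  "HIS": {
    "one": "H",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "ND1": "N", "CD2": "C", "CE1": "C", "NE2": "N"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "ND1"], ["ND1", "CE1"], ["CE1", "NE2"], ["NE2", "CD2"], ["CD2", "CG"]]
  },
  "ILE": {
    "one": "I",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG1": "C", "CG2": "C", "CD1": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG1"], ["CB", "CG2"], ["CG1", "CD1"]]
  },
  "LEU": {
    "one": "L",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD1": "C", "CD2": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD1"], ["CG", "CD2"]]
  },
  "LYS": {
    "one": "K",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD": "C", "CE": "C", "NZ": "N"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD"], ["CD", "CE"], ["CE", "NZ"]]
  },
  "MET": {
    "one": "M",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "SD": "S", "CE": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "SD"], ["SD", "CE"]]
  },
  "PHE": {
    "one": "F",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD1": "C", "CD2": "C", "CE1": "C", "CE2": "C", "CZ": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD1"], ["CD1", "CE1"], ["CE1", "CZ"], ["CZ", "CE2"], ["CE2", "CD2"], ["CD2", "CG"]]
  },
  "PRO": {
    "one": "P",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD"], ["CD", "N"]]
  },
  "SER": {
    "one": "S",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG": "O"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "OG"]]
  },
  "THR": {
    "one": "T",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG1": "O", "CG2": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "OG1"], ["CB", "CG2"]]
  },
  "TRP": {
    "one": "W",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD1": "C", "CD2": "C", "NE1": "N", "CE2": "C", "CE3": "C", "CZ2": "C", "CZ3": "C", "CH2": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD1"], ["CD1", "NE1"], ["NE1", "CE2"], ["CE2", "CD2"], ["CD2", "CG"], ["CD2", "CE3"], ["CE3", "CZ3"], ["CZ3", "CH2"], ["CH2", "CZ2"], ["CZ2", "CE2"]]
  },
  "TYR": {
    "one": "Y",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C", "CD1": "C", "CD2": "C", "CE1": "C", "CE2": "C", "CZ": "C", "OH": "O"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG"], ["CG", "CD1"], ["CD1", "CE1"], ["CE1", "CZ"], ["CZ", "CE2"], ["CE2", "CD2"], ["CD2", "CG"], ["CZ", "OH"]]
  },
  "VAL": {
    "one": "V",
    "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG1": "C", "CG2": "C"},
    "bonds": [["N", "CA"], ["CA", "C"], ["C", "O"], ["CA", "CB"], ["CB", "CG1"], ["CB", "CG2"]]
  }
}
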
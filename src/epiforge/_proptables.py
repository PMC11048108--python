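"""Physicochemical constant tables.

Provenance:
- DIPEPTIDE_INSTABILITY: dipeptide instability weight values (DIWV) of
  Guruprasad, Reddy & Pandit (1990), Protein Eng. 4:155-161, as used by the
  ExPASy ProtParam instability index.
- KYTE_DOOLITTLE: hydropathy scale of Kyte & Doolittle (1982), J Mol Biol
  157:105-132.
- ALIPHATIC coefficients: Ikai (1980), J Biochem 88:1895-1898.
- PKA_*: reduced Bjellqvist-style pKa set as applied by ProtParam-derived
  isoelectric-point calculators (flat N-terminal pKa).
- HALF_LIFE_MAMMALIAN_H: N-end-rule half-lives in mammalian reticulocytes
  (Bachmair, Finley & Varshavsky 1986; ProtParam's mammalian column), hours.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# aliphatic index = X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu), X in mole percent
ALIPHATIC_COEFF = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}

HALF_LIFE_MAMMALIAN_H = {
    "A": 4.4, "R": 1.0, "N": 1.4, "D": 1.1, "C": 1.2,
    "Q": 0.8, "E": 1.0, "G": 30.0, "H": 3.5, "I": 20.0,
    "L": 5.5, "K": 1.3, "M": 30.0, "F": 1.1, "P": 20.0,
    "S": 1.9, "T": 7.2, "W": 2.8, "Y": 2.8, "V": 100.0,
}

# ionizable groups; positive groups contribute +1 below their pKa,
# negative groups -1 above theirs. Terminal pKas depend on the terminal
# residue for a handful of residues (Bjellqvist's tables).
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}

DIPEPTIDE_INSTABILITY = {
    "A": {"A": 1, "C": 44.94, "D": -7.49, "E": 1, "F": 1, "G": 1, "H": -7.49, "I": 1, "K": 1, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 1, "R": 1, "S": 1, "T": 1, "V": 1, "W": 1, "Y": 1},
    "C": {"A": 1, "C": 1, "D": 20.26, "E": 1, "F": 1, "G": 1, "H": 33.6, "I": 1, "K": 1, "L": 20.26, "M": 33.6, "N": 1, "P": 20.26, "Q": -6.54, "R": 1, "S": 1, "T": 33.6, "V": -6.54, "W": 24.68, "Y": 1},
    "D": {"A": 1, "C": 1, "D": 1, "E": 1, "F": -6.54, "G": 1, "H": 1, "I": 1, "K": -7.49, "L": 1, "M": 1, "N": 1, "P": 1, "Q": 1, "R": -6.54, "S": 20.26, "T": -14.03, "V": 1, "W": 1, "Y": 1},
    "E": {"A": 1, "C": 44.94, "D": 20.26, "E": 33.6, "F": 1, "G": 1, "H": -6.54, "I": 20.26, "K": 1, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 20.26, "R": 1, "S": 20.26, "T": 1, "V": 1, "W": -14.03, "Y": 1},
    "F": {"A": 1, "C": 1, "D": 13.34, "E": 1, "F": 1, "G": 1, "H": 1, "I": 1, "K": -14.03, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 1, "R": 1, "S": 1, "T": 1, "V": 1, "W": 1, "Y": 33.601},
    "G": {"A": -7.49, "C": 1, "D": 1, "E": -6.54, "F": 1, "G": 13.34, "H": 1, "I": -7.49, "K": -7.49, "L": 1, "M": 1, "N": -7.49, "P": 1, "Q": 1, "R": 1, "S": 1, "T": -7.49, "V": 1, "W": 13.34, "Y": -7.49},
    "H": {"A": 1, "C": 1, "D": 1, "E": 1, "F": -9.37, "G": -9.37, "H": 1, "I": 44.94, "K": 24.68, "L": 1, "M": 1, "N": 24.68, "P": -1.88, "Q": 1, "R": 1, "S": 1, "T": -6.54, "V": 1, "W": -1.88, "Y": 44.94},
    "I": {"A": 1, "C": 1, "D": 1, "E": 44.94, "F": 1, "G": 1, "H": 13.34, "I": 1, "K": -7.49, "L": 20.26, "M": 1, "N": 1, "P": -1.88, "Q": 1, "R": 1, "S": 1, "T": 1, "V": -7.49, "W": 1, "Y": 1},
    "K": {"A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": -7.49, "H": 1, "I": -7.49, "K": 1, "L": -7.49, "M": 33.6, "N": 1, "P": -6.54, "Q": 24.64, "R": 33.6, "S": 1, "T": 1, "V": -7.49, "W": 1, "Y": 1},
    "L": {"A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1, "H": 1, "I": 1, "K": -7.49, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 33.6, "R": 20.26, "S": 1, "T": 1, "V": 1, "W": 24.68, "Y": 1},
    "M": {"A": 13.34, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1, "H": 58.28, "I": 1, "K": 1, "L": 1, "M": -1.88, "N": 1, "P": 44.94, "Q": -6.54, "R": -6.54, "S": 44.94, "T": -1.88, "V": 1, "W": 1, "Y": 24.68},
    "N": {"A": 1, "C": -1.88, "D": 1, "E": 1, "F": -14.03, "G": -14.03, "H": 1, "I": 44.94, "K": 24.68, "L": 1, "M": 1, "N": 1, "P": -1.88, "Q": -6.54, "R": 1, "S": 1, "T": -7.49, "V": 1, "W": -9.37, "Y": 1},
    "P": {"A": 20.26, "C": -6.54, "D": -6.54, "E": 18.38, "F": 20.26, "G": 1, "H": 1, "I": 1, "K": 1, "L": 1, "M": -6.54, "N": 1, "P": 20.26, "Q": 20.26, "R": -6.54, "S": 20.26, "T": 1, "V": 20.26, "W": -1.88, "Y": 1},
    "Q": {"A": 1, "C": -6.54, "D": 20.26, "E": 20.26, "F": -6.54, "G": 1, "H": 1, "I": 1, "K": 1, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 20.26, "R": 1, "S": 44.94, "T": 1, "V": -6.54, "W": 1, "Y": -6.54},
    "R": {"A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": -7.49, "H": 20.26, "I": 1, "K": 1, "L": 1, "M": 1, "N": 13.34, "P": 20.26, "Q": 20.26, "R": 58.28, "S": 44.94, "T": 1, "V": 1, "W": 58.28, "Y": -6.54},
    "S": {"A": 1, "C": 33.6, "D": 1, "E": 20.26, "F": 1, "G": 1, "H": 1, "I": 1, "K": 1, "L": 1, "M": 1, "N": 1, "P": 44.94, "Q": 20.26, "R": 20.26, "S": 20.26, "T": 1, "V": 1, "W": 1, "Y": 1},
    "T": {"A": 1, "C": 1, "D": 1, "E": 20.26, "F": 13.34, "G": -7.49, "H": 1, "I": 1, "K": 1, "L": 1, "M": 1, "N": -14.03, "P": 1, "Q": -6.54, "R": 1, "S": 1, "T": 1, "V": 1, "W": -14.03, "Y": 1},
    "V": {"A": 1, "C": 1, "D": -14.03, "E": 1, "F": 1, "G": -7.49, "H": 1, "I": 1, "K": -1.88, "L": 1, "M": 1, "N": 1, "P": 20.26, "Q": 1, "R": 1, "S": 1, "T": -7.49, "V": 1, "W": 1, "Y": -6.54},
    "W": {"A": -14.03, "C": 1, "D": 1, "E": 1, "F": 1, "G": -9.37, "H": 24.68, "I": 1, "K": 1, "L": 13.34, "M": 24.68, "N": 13.34, "P": 1, "Q": 1, "R": 1, "S": 1, "T": -14.03, "V": -7.49, "W": 1, "Y": 1},
    "Y": {"A": 24.68, "C": 1, "D": 24.68, "E": -6.54, "F": 1, "G": -7.49, "H": 13.34, "I": 1, "K": 1, "L": 1, "M": 44.94, "N": 1, "P": 13.34, "Q": 1, "R": -15.91, "S": 1, "T": -7.49, "V": 1, "W": -9.37, "Y": 13.34},
}
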
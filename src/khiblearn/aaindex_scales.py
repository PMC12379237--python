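"""Default amino-acid property scales for position-specific encoding.

Twenty numerical scales over the 20 standard residues, chosen to cover the
property families most relevant to acyl-modification chemistry:
hydrophobicity/hydrophilicity, residue size and steric bulk, polarity and
charge, electronic properties (EIIP), secondary-structure propensity,
flexibility, accessibility, mutability and information content.  Values are
taken from the standard published tables named in each key.  The set is a
documented default, not a curated claim: any 20-scale table supplied via
:func:`khiblearn.encoders.read_aaindex_table` replaces it.
"""

from __future__ import annotations

import math

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid in the standard genetic code (for the information scale)
_N_CODONS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

DEFAULT_SCALES: dict[str, dict[str, float]] = {
    # Kyte & Doolittle (1982) hydropathy
    "hydropathy_kd": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    # Hopp & Woods (1981) hydrophilicity
    "hydrophilicity_hw": {
        "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
        "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
        "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
        "Y": -2.3, "V": -1.5,
    },
    # Eisenberg consensus hydrophobicity (1984)
    "hydrophobicity_eisenberg": {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
        "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
        "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
        "Y": 0.26, "V": 1.08,
    },
    # Fauchere & Pliska (1983) octanol/water transfer free energy
    "transfer_energy_fp": {
        "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54, "Q": -0.22,
        "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80, "L": 1.70, "K": -0.99,
        "M": 1.23, "F": 1.79, "P": 0.72, "S": -0.04, "T": 0.26, "W": 2.25,
        "Y": 0.96, "V": 1.22,
    },
    # Grantham (1974) polarity
    "polarity_grantham": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
        "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
        "Y": 6.2, "V": 5.9,
    },
    # net side-chain charge at physiological pH (His partial)
    "net_charge": {
        "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0,
        "E": -1.0, "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0,
        "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
        "Y": 0.0, "V": 0.0,
    },
    # isoelectric point of the free amino acid
    "isoelectric_point": {
        "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
        "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
        "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
        "Y": 5.66, "V": 5.96,
    },
    # Zamyatnin (1972) residue volume, A^3
    "residue_volume": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
        "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
        "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
        "Y": 193.6, "V": 140.0,
    },
    # residue molecular weight, Da
    "molecular_weight": {
        "A": 89.1, "R": 174.2, "N": 132.1, "D": 133.1, "C": 121.2, "Q": 146.2,
        "E": 147.1, "G": 75.1, "H": 155.2, "I": 131.2, "L": 131.2, "K": 146.2,
        "M": 149.2, "F": 165.2, "P": 115.1, "S": 105.1, "T": 119.1, "W": 204.2,
        "Y": 181.2, "V": 117.1,
    },
    # Zimmerman (1968) bulkiness
    "bulkiness": {
        "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46, "Q": 14.45,
        "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40, "L": 21.40, "K": 15.71,
        "M": 16.25, "F": 19.80, "P": 17.43, "S": 9.47, "T": 15.77, "W": 21.67,
        "Y": 18.03, "V": 21.57,
    },
    # Charton & Charton (1982) polarizability
    "polarizability": {
        "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128, "Q": 0.180,
        "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186, "L": 0.186, "K": 0.219,
        "M": 0.221, "F": 0.290, "P": 0.131, "S": 0.062, "T": 0.108, "W": 0.409,
        "Y": 0.298, "V": 0.140,
    },
    # Jones (1975) refractivity
    "refractivity": {
        "A": 4.34, "R": 26.66, "N": 13.28, "D": 12.00, "C": 35.77, "Q": 17.56,
        "E": 17.26, "G": 0.00, "H": 21.81, "I": 19.06, "L": 18.78, "K": 21.29,
        "M": 21.64, "F": 29.40, "P": 10.93, "S": 6.35, "T": 11.01, "W": 42.53,
        "Y": 31.53, "V": 13.92,
    },
    # Veljkovic electron-ion interaction potential (EIIP)
    "eiip": {
        "A": 0.0373, "R": 0.0959, "N": 0.0036, "D": 0.1263, "C": 0.0829,
        "Q": 0.0761, "E": 0.0058, "G": 0.0050, "H": 0.0242, "I": 0.0000,
        "L": 0.0000, "K": 0.0371, "M": 0.0823, "F": 0.0946, "P": 0.0198,
        "S": 0.0829, "T": 0.0941, "W": 0.0548, "Y": 0.0516, "V": 0.0057,
    },
    # Bhaskaran & Ponnuswamy (1988) average flexibility
    "flexibility": {
        "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493,
        "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466,
        "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305,
        "Y": 0.420, "V": 0.386,
    },
    # Chothia (1976) residue accessible surface area in tripeptide, A^2
    "accessible_surface": {
        "A": 115.0, "R": 225.0, "N": 160.0, "D": 150.0, "C": 135.0, "Q": 180.0,
        "E": 190.0, "G": 75.0, "H": 195.0, "I": 175.0, "L": 170.0, "K": 200.0,
        "M": 185.0, "F": 210.0, "P": 145.0, "S": 115.0, "T": 140.0, "W": 255.0,
        "Y": 230.0, "V": 155.0,
    },
    # Chou & Fasman (1978) alpha-helix propensity
    "helix_propensity_cf": {
        "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
        "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
        "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
        "Y": 0.69, "V": 1.06,
    },
    # Chou & Fasman (1978) beta-sheet propensity
    "sheet_propensity_cf": {
        "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
        "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
        "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
        "Y": 1.47, "V": 1.70,
    },
    # Chou & Fasman (1978) beta-turn propensity
    "turn_propensity_cf": {
        "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19, "Q": 0.98,
        "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47, "L": 0.59, "K": 1.01,
        "M": 0.60, "F": 0.60, "P": 1.52, "S": 1.43, "T": 0.96, "W": 0.96,
        "Y": 1.14, "V": 0.50,
    },
    # Dayhoff relative mutability
    "relative_mutability": {
        "A": 100.0, "R": 65.0, "N": 134.0, "D": 106.0, "C": 20.0, "Q": 93.0,
        "E": 102.0, "G": 49.0, "H": 66.0, "I": 96.0, "L": 40.0, "K": 56.0,
        "M": 94.0, "F": 41.0, "P": 56.0, "S": 120.0, "T": 97.0, "W": 18.0,
        "Y": 41.0, "V": 74.0,
    },
    # information content from codon degeneracy: -log2(n_codons / 61)
    "codon_information": {
        aa: -math.log2(n / 61.0) for aa, n in _N_CODONS.items()
    },
}
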
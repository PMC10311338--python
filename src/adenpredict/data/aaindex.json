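{
  "comment": "Per-residue physicochemical descriptors used by the physiochemical encoding scheme: 12 AAindex descriptors plus the 3 Hellberg z-scales (hydrophobicity, size/steric bulk, electronic properties). Each descriptor is z-standardized across the 20 canonical residues before use, so only relative values matter. The AAindex set is an editable default covering hydropathy, polarity, volume, charge-related, surface and secondary-structure propensities; swap accessions here to change the scheme.",
  "aaindex": {
    "KYTJ820101": {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2},
    "GRAR740102": {"A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9},
    "GRAR740103": {"A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0, "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0, "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0, "Y": 136.0, "V": 84.0},
    "ZIMJ680104": {"A": 6.0, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.3, "S": 5.68, "T": 5.66, "W": 5.89, "Y": 5.66, "V": 5.96},
    "FASG760101": {"A": 89.09, "R": 174.2, "N": 132.12, "D": 133.1, "C": 121.15, "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17, "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13, "S": 105.09, "T": 119.12, "W": 204.24, "Y": 181.19, "V": 117.15},
    "CHOC760101": {"A": 115.0, "R": 225.0, "N": 160.0, "D": 150.0, "C": 135.0, "Q": 180.0, "E": 190.0, "G": 75.0, "H": 195.0, "I": 175.0, "L": 170.0, "K": 200.0, "M": 185.0, "F": 210.0, "P": 145.0, "S": 115.0, "T": 140.0, "W": 255.0, "Y": 230.0, "V": 155.0},
    "FAUJ880103": {"A": 1.0, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43, "Q": 3.95, "E": 3.78, "G": 0.0, "H": 4.66, "I": 4.0, "L": 4.0, "K": 4.77, "M": 4.43, "F": 5.89, "P": 2.72, "S": 1.6, "T": 2.6, "W": 8.08, "Y": 6.47, "V": 3.0},
    "CHOP780201": {"A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.7, "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.0, "I": 1.08, "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06},
    "CHOP780202": {"A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.1, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.6, "L": 1.3, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.7},
    "JANJ780101": {"A": 27.8, "R": 94.7, "N": 60.1, "D": 60.6, "C": 15.5, "Q": 68.7, "E": 68.2, "G": 24.5, "H": 50.7, "I": 22.8, "L": 27.6, "K": 103.0, "M": 33.5, "F": 25.5, "P": 51.5, "S": 42.0, "T": 45.0, "W": 34.7, "Y": 55.2, "V": 23.7},
    "HOPT810101": {"A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5},
    "EISD840101": {"A": 0.62, "R": -2.53, "N": -0.78, "D": -0.9, "C": 0.29, "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.4, "I": 1.38, "L": 1.06, "K": -1.5, "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08}
  },
  "zscales": {
    "z1": {"A": 0.07, "R": 2.88, "N": 3.22, "D": 3.64, "C": 0.71, "Q": 2.18, "E": 3.08, "G": 2.23, "H": 2.41, "I": -4.44, "L": -4.19, "K": 2.84, "M": -2.49, "F": -4.92, "P": -1.22, "S": 1.96, "T": 0.92, "W": -4.75, "Y": -1.39, "V": -2.69},
    "z2": {"A": -1.73, "R": 2.52, "N": 1.45, "D": 1.13, "C": -0.97, "Q": 0.53, "E": 0.39, "G": -5.36, "H": 1.74, "I": -1.68, "L": -1.03, "K": 1.41, "M": -0.27, "F": 1.3, "P": 0.88, "S": -1.63, "T": -2.09, "W": 3.65, "Y": 2.32, "V": -2.53},
    "z3": {"A": 0.09, "R": -3.44, "N": 0.84, "D": 2.36, "C": 4.13, "Q": -1.14, "E": -0.07, "G": 0.3, "H": 1.11, "I": -1.03, "L": -0.98, "K": -3.14, "M": -0.41, "F": 0.45, "P": 2.23, "S": 0.57, "T": -1.4, "W": 0.85, "Y": 0.01, "V": -1.29}
  }
}
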
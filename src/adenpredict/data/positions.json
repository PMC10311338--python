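{
  "comment": "Default binding-pocket position set: 34 match-state indices (1-based) of an AMP-binding profile HMM whose aligned residues are concatenated into the length-34 A-domain signature. This default follows the extended binding-pocket convention (residues lining the substrate pocket of the phenylalanine-activating reference A-domain mapped onto profile match states) and should be validated or replaced when a curated position set for the user's exact profile version is available. Positions must be distinct and within the profile's match-state count.",
  "reference_profile": "AMP-binding (PF00501-style)",
  "positions": [186, 187, 188, 189, 195, 196, 197, 198, 199, 200, 201, 224, 225, 226, 227, 228, 229, 230, 231, 252, 253, 254, 255, 256, 270, 271, 272, 273, 274, 275, 297, 298, 299, 322]
}
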
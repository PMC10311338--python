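"""Shared constants for the signature-based prediction pipeline."""

#: Canonical amino acids, in fixed alphabetical order. This order defines the
#: within-block offsets of the one-hot encoding and must not change once
#: models have been persisted.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Number of binding-pocket residues in an A-domain signature.
SIGNATURE_LENGTH = 34

#: Characters permitted in a signature besides the canonical amino acids:
#: 'X' for an ambiguous residue in the input protein, '-' for a profile match
#: state that fell in a deletion.
GAP = "-"
UNKNOWN = "X"

SIGNATURE_ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {UNKNOWN}
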
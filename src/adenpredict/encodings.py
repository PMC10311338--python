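"""Numeric encodings of binding-pocket signatures.

Three interchangeable schemes map a length-34 signature to a fixed-length
feature vector by concatenating one block per residue:

* ``onehot`` — each residue becomes a 20-length indicator vector
  (block offset = alphabetical index), giving 680 features.
* ``physiochemical`` — each residue becomes 12 AAindex descriptors plus the
  3 z-scales (hydrophobicity, size, electronic properties), giving 510
  features. Each descriptor is z-standardized across the 20 canonical
  residues, so the encoding is dataset-independent.
* ``external`` — per-residue feature rows supplied by the user (e.g.
  structure-derived property predictions), one row per (id, position).

``'-'`` (deletion) and ``'X'`` (ambiguous) encode as all-zero blocks in
every scheme; under standardized physiochemical features zero is the
residue-population mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import AMINO_ACIDS, GAP, SIGNATURE_LENGTH, UNKNOWN
from .signatures import Signature

ONEHOT_DIM = len(AMINO_ACIDS)  # 20
PHYSIOCHEMICAL_DIM = 15  # 12 AAindex + 3 z-scales


@dataclass(frozen=True)
class EncodingScheme:
    """A per-residue numeric mapping applied position-wise to signatures."""

    name: str
    per_residue_dim: int
    residue_table: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.residue_table)
        if missing:
            raise ValueError(f"residue table missing {sorted(missing)}")
        for aa, vec in self.residue_table.items():
            if len(vec) != self.per_residue_dim:
                raise ValueError(
                    f"residue {aa!r}: vector length {len(vec)} != "
                    f"per_residue_dim {self.per_residue_dim}"
                )

    @property
    def vector_length(self) -> int:
        return SIGNATURE_LENGTH * self.per_residue_dim


def onehot_scheme() -> EncodingScheme:
    """Indicator encoding over the fixed alphabet ``ACDEFGHIKLMNPQRSTVWY``."""
    table = {
        aa: np.eye(ONEHOT_DIM)[i] for i, aa in enumerate(AMINO_ACIDS)
    }
    return EncodingScheme("onehot", ONEHOT_DIM, table)


def _standardize(values: dict[str, float], name: str) -> dict[str, float]:
    arr = np.array([values[aa] for aa in AMINO_ACIDS], dtype=float)
    sd = arr.std()  # population SD over the 20 residues
    if sd == 0.0:
        raise ValueError(f"descriptor {name!r} is constant across residues")
    arr = (arr - arr.mean()) / sd
    return dict(zip(AMINO_ACIDS, arr))


def build_physiochemical_scheme(
    aaindex: Mapping[str, Mapping[str, float]] | None = None,
    zscales: Mapping[str, Mapping[str, float]] | None = None,
) -> EncodingScheme:
    """Build the 15-descriptor physiochemical scheme.

    Parameters default to the packaged descriptor config (12 AAindex tables
    plus the 3 z-scales). Each descriptor must supply a value for all 20
    canonical residues and is standardized to zero mean / unit variance
    across them; a constant descriptor is rejected as a config mistake.
    """
    if aaindex is None or zscales is None:
        doc = json.loads(files("adenpredict.data").joinpath("aaindex.json").read_text())
        if aaindex is None:
            aaindex = doc["aaindex"]
        if zscales is None:
            zscales = doc["zscales"]
    if len(aaindex) != 12:
        raise ValueError(f"expected 12 AAindex descriptors, got {len(aaindex)}")
    if len(zscales) != 3:
        raise ValueError(f"expected 3 z-scale descriptors, got {len(zscales)}")

    rows: list[dict[str, float]] = []
    for name, values in list(aaindex.items()) + list(zscales.items()):
        missing = set(AMINO_ACIDS) - set(values)
        if missing:
            raise ValueError(f"descriptor {name!r} missing residue(s) {sorted(missing)}")
        rows.append(_standardize(values, name))

    table = {
        aa: np.array([row[aa] for row in rows]) for aa in AMINO_ACIDS
    }
    return EncodingScheme("physiochemical", PHYSIOCHEMICAL_DIM, table)


def get_scheme(name: str) -> EncodingScheme:
    if name == "onehot":
        return onehot_scheme()
    if name == "physiochemical":
        return build_physiochemical_scheme()
    raise ValueError(f"unknown encoding scheme {name!r}")


def encode(signature: Signature | str, scheme: EncodingScheme) -> np.ndarray:
    """Encode one signature as a length ``34 * per_residue_dim`` vector."""
    residues = signature.residues if isinstance(signature, Signature) else signature
    if len(residues) != SIGNATURE_LENGTH:
        raise ValueError(f"signature length {len(residues)} != {SIGNATURE_LENGTH}")
    zero = np.zeros(scheme.per_residue_dim)
    blocks = []
    for aa in residues:
        if aa in (GAP, UNKNOWN):
            blocks.append(zero)
        elif aa in scheme.residue_table:
            blocks.append(scheme.residue_table[aa])
        else:
            raise ValueError(f"unknown residue {aa!r} in signature")
    return np.concatenate(blocks)


def encode_all(
    signatures: Sequence[Signature | str], scheme: EncodingScheme
) -> np.ndarray:
    """Encode a batch into an ``(n, 34 * per_residue_dim)`` matrix."""
    if not signatures:
        return np.empty((0, scheme.vector_length))
    return np.vstack([encode(s, scheme) for s in signatures])


def decode_onehot(vector: np.ndarray) -> str:
    """Recover the signature string from a one-hot vector (gaps -> '-')."""
    blocks = np.asarray(vector).reshape(SIGNATURE_LENGTH, ONEHOT_DIM)
    out = []
    for block in blocks:
        if block.sum() == 0:
            out.append(GAP)
        else:
            out.append(AMINO_ACIDS[int(np.argmax(block))])
    return "".join(out)


def load_external_features(
    table: str | Path | pd.DataFrame, ids: Sequence[str]
) -> np.ndarray:
    """Assemble per-signature vectors from a per-residue feature table.

    The table (TSV with header ``id``, ``position``, then feature columns)
    must contain one row for every (id, position 1..34) pair of the requested
    ids. Vectors have length ``34 * D`` where ``D`` is the feature-column
    count.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t")
    if list(table.columns[:2]) != ["id", "position"]:
        raise ValueError("external feature table must start with columns id, position")
    feat_cols = list(table.columns[2:])
    if not feat_cols:
        raise ValueError("external feature table has no feature columns")
    if table[feat_cols].isna().any().any():
        raise ValueError("ragged feature table: missing values in feature columns")

    indexed = table.set_index(["id", "position"])
    if indexed.index.has_duplicates:
        raise ValueError("duplicate (id, position) rows in feature table")

    vectors = []
    for rid in ids:
        blocks = []
        for pos in range(1, SIGNATURE_LENGTH + 1):
            try:
                row = indexed.loc[(rid, pos)]
            except KeyError:
                raise ValueError(
                    f"feature table missing row for id {rid!r} position {pos}"
                ) from None
            blocks.append(np.asarray(row, dtype=float))
        vectors.append(np.concatenate(blocks))
    return np.vstack(vectors) if vectors else np.empty((0, SIGNATURE_LENGTH * len(feat_cols)))
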
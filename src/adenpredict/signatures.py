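"""Extraction of binding-pocket signatures from A-domain protein sequences.

An adenylation (A) domain selects which amino-acid monomer an NRPS module
activates. Its specificity is well approximated by a small set of residues
lining the substrate binding pocket. This module aligns full-length A-domain
sequences to an AMP-binding profile HMM and reads off the residues at 34
configured match states — the extended binding-pocket signature that all
downstream prediction operates on.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyhmmer import easel, plan7

from ._constants import GAP, SEQUENCE_ALPHABET, SIGNATURE_ALPHABET, SIGNATURE_LENGTH

logger = logging.getLogger(__name__)

DEFAULT_EVALUE = 1e-5


class NoDomainHitError(ValueError):
    """Raised when a sequence has no significant alignment to the profile."""


@dataclass(frozen=True)
class ADomainRecord:
    """A raw A-domain protein sequence.

    Parameters
    ----------
    id : str
        Free-text sequence identifier (e.g. the FASTA header token).
    sequence : str
        Protein sequence over the 20 canonical amino acids plus ``X``.
    source : str, optional
        Free-text provenance such as a genome or protein accession.
    """

    id: str
    sequence: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}; "
                "allowed are the 20 canonical amino acids and X"
            )


@dataclass(frozen=True)
class SignaturePositions:
    """The 34 profile match states whose residues form the signature.

    Indices are 1-based into the match states of the reference profile HMM.
    The signature concatenates residues in the order listed here.
    """

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != SIGNATURE_LENGTH:
            raise ValueError(
                f"need exactly {SIGNATURE_LENGTH} positions, got {len(self.positions)}"
            )
        if len(set(self.positions)) != SIGNATURE_LENGTH:
            raise ValueError("signature positions must be distinct")
        if min(self.positions) < 1:
            raise ValueError("signature positions are 1-based; found index < 1")

    def validate_for_profile(self, hmm: plan7.HMM) -> None:
        if max(self.positions) > hmm.M:
            raise ValueError(
                f"position {max(self.positions)} exceeds profile match-state "
                f"count {hmm.M}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SignaturePositions":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(tuple(doc["positions"]))

    @classmethod
    def default(cls) -> "SignaturePositions":
        from importlib.resources import files

        doc = json.loads(files("adenpredict.data").joinpath("positions.json").read_text())
        return cls(tuple(doc["positions"]))


@dataclass(frozen=True)
class Signature:
    """A length-34 binding-pocket residue string."""

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != SIGNATURE_LENGTH:
            raise ValueError(
                f"signature must have length {SIGNATURE_LENGTH}, got {len(self.residues)}"
            )
        bad = set(self.residues) - SIGNATURE_ALPHABET
        if bad:
            raise ValueError(f"invalid signature character(s) {sorted(bad)!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues


@dataclass(frozen=True)
class LabeledSignature:
    """A signature together with its substrate monomer label.

    Labels are normalized lowercase tokens such as ``"phe"``, ``"ser"``,
    ``"orn"`` or ``"dhb"``.
    """

    signature: Signature
    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("empty substrate label")


@dataclass(frozen=True)
class SignatureHit:
    """One extracted signature with its alignment envelope on the query."""

    id: str
    start: int  # 1-based, inclusive, on the query protein
    end: int
    signature: Signature


def load_hmm(path: str | Path) -> plan7.HMM:
    """Load the first profile from a HMMER3 file (ASCII or binary)."""
    with plan7.HMMFile(str(path)) as fh:
        return fh.read()


def _alignment_match_residues(ali: "plan7.Alignment") -> dict[int, str]:
    """Map 1-based match-state index -> aligned query residue ('-' at deletions).

    The alignment strings pair profile consensus characters with query
    characters column by column; consensus '.' marks insert columns, which
    consume query residues but no match state.
    """
    out: dict[int, str] = {}
    state = ali.hmm_from
    for hc, tc in zip(ali.hmm_sequence, ali.target_sequence):
        if hc == ".":
            continue  # insertion relative to the profile
        out[state] = GAP if tc == "-" else tc.upper()
        state += 1
    return out


def _hits_for_record(
    record: ADomainRecord,
    hmm: plan7.HMM,
    positions: SignaturePositions,
    evalue: float,
) -> list[SignatureHit]:
    positions.validate_for_profile(hmm)
    alphabet = hmm.alphabet
    seq = easel.TextSequence(
        name=record.id.encode(), sequence=record.sequence.upper()
    ).digitize(alphabet)
    pipeline = plan7.Pipeline(alphabet)
    tophits = pipeline.search_hmm(hmm, easel.DigitalSequenceBlock(alphabet, [seq]))

    domains = [
        dom
        for hit in tophits
        for dom in hit.domains
        if dom.i_evalue <= evalue
    ]
    domains.sort(key=lambda d: d.env_from)

    hits: list[SignatureHit] = []
    multi = len(domains) > 1
    for idx, dom in enumerate(domains, start=1):
        residues = _alignment_match_residues(dom.alignment)
        sig = "".join(residues.get(p, GAP) for p in positions.positions)
        hit_id = record.id
        if multi:
            hit_id = f"{record.id}|hit{idx}:{dom.env_from}-{dom.env_to}"
        hits.append(
            SignatureHit(
                id=hit_id,
                start=dom.env_from,
                end=dom.env_to,
                signature=Signature(sig),
            )
        )
    return hits


def extract_signature(
    record: ADomainRecord,
    hmm: plan7.HMM,
    positions: SignaturePositions | None = None,
    evalue: float = DEFAULT_EVALUE,
) -> Signature:
    """Extract the binding-pocket signature of one A-domain.

    The record is aligned to the profile HMM; the residues aligned to the 34
    configured match states are concatenated in position order. A match state
    that falls inside a deletion, or outside the aligned region, contributes
    ``'-'``. When several domains in the protein pass the E-value threshold,
    the best-scoring one is used (use :func:`extract_all` to keep all hits).

    Raises
    ------
    NoDomainHitError
        If no domain alignment passes the per-domain E-value threshold.
    """
    if positions is None:
        positions = SignaturePositions.default()
    hits = _hits_for_record(record, hmm, positions, evalue)
    if not hits:
        raise NoDomainHitError(
            f"no A-domain hit: record {record.id!r} has no alignment with "
            f"domain E-value <= {evalue:g}"
        )
    return hits[0].signature


def extract_all(
    records: Iterable[ADomainRecord],
    hmm: plan7.HMM,
    positions: SignaturePositions | None = None,
    evalue: float = DEFAULT_EVALUE,
) -> list[SignatureHit]:
    """Extract signatures for a batch of records, skipping non-matching ones.

    Every domain hit above threshold yields its own row (ids of secondary
    hits are suffixed with the hit index and envelope coordinates). Records
    with no hit are logged and skipped; input order is preserved.
    """
    if positions is None:
        positions = SignaturePositions.default()
    out: list[SignatureHit] = []
    for record in records:
        hits = _hits_for_record(record, hmm, positions, evalue)
        if not hits:
            logger.warning("no A-domain hit for record %r; skipped", record.id)
            continue
        out.extend(hits)
    return out


def deduplicate(data: Sequence[LabeledSignature]) -> list[LabeledSignature]:
    """Collapse identical signatures to one labeled datapoint each.

    Duplicates sharing a label keep one representative. Conflicting labels
    are resolved by majority vote; exact ties are dropped with a warning
    (their specificity cannot be decided from the data). Output is sorted by
    signature string, so the operation is deterministic and idempotent.
    """
    by_sig: dict[str, Counter[str]] = {}
    for item in data:
        by_sig.setdefault(item.signature.residues, Counter())[item.label] += 1

    out: list[LabeledSignature] = []
    for sig in sorted(by_sig):
        counts = by_sig[sig]
        best = counts.most_common()
        if len(best) > 1 and best[0][1] == best[1][1]:
            tied = sorted(label for label, n in best if n == best[0][1])
            logger.warning(
                "signature %s dropped: tied labels %s", sig, ",".join(tied)
            )
            continue
        out.append(LabeledSignature(Signature(sig), best[0][0]))
    return out


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path) -> list[ADomainRecord]:
    """Read protein FASTA into records (id = first header token)."""
    records: list[ADomainRecord] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append(ADomainRecord(header, "".join(chunks)))
                header = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        records.append(ADomainRecord(header, "".join(chunks)))
    return records


def write_signature_tsv(hits: Sequence[SignatureHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tsignature\n")
        for h in hits:
            fh.write(f"{h.id}\t{h.start}\t{h.end}\t{h.signature.residues}\n")


def read_signature_tsv(path: str | Path) -> list[SignatureHit]:
    hits: list[SignatureHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["id", "start", "end", "signature"]:
            raise ValueError(f"unexpected signature TSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            rid, start, end, sig = line.rstrip("\n").split("\t")[:4]
            hits.append(SignatureHit(rid, int(start), int(end), Signature(sig)))
    return hits


def write_labeled_tsv(data: Sequence[LabeledSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("signature\tlabel\n")
        for item in data:
            fh.write(f"{item.signature.residues}\t{item.label}\n")


def read_labeled_tsv(path: str | Path) -> list[LabeledSignature]:
    data: list[LabeledSignature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["signature", "label"]:
            raise ValueError(f"unexpected labeled TSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            sig, label = line.rstrip("\n").split("\t")[:2]
            data.append(LabeledSignature(Signature(sig), label.lower()))
    return data
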
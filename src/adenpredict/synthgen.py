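"""Synthetic labeled-signature datasets and toy alignment fixtures.

Real labeled A-domain collections are external downloads, so every other
module is exercised against generated data that mimics their shape: labeled
length-34 signatures in which a subset of "motif" positions carry a
class-specific residue with tunable probability (``motif_strength``), over a
background residue distribution. Class imbalance, class count and motif
informativeness are all controllable, which lets tests plant a known
structure (a Bayes rule, a cluster partition, an exact Hamming distance)
and check that the pipeline recovers it.

The toy profile generator emits a small HMMER3 profile together with
sequences threaded through it with known insertions and deletions, plus the
ground-truth signature of each sequence — an end-to-end oracle for the
extraction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pyhmmer import easel, plan7

from ._constants import AMINO_ACIDS, SIGNATURE_LENGTH
from .signatures import LabeledSignature, Signature, SignaturePositions

_N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic labeled signature dataset.

    ``motif_positions`` are 1-based signature positions whose residue
    depends on the class; each class draws one specific residue per motif
    position (distinct across classes), carried with probability
    ``motif_strength`` and replaced by a background draw otherwise. All
    non-motif positions are background draws (uniform over the 20 residues
    by default).
    """

    n_classes: int
    n_per_class: tuple[int, ...]
    motif_positions: tuple[int, ...]
    motif_strength: float = 1.0
    seed: int = 0
    background: tuple[float, ...] | None = None  # length-20 distribution
    label_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_classes > _N_AA:
            raise ValueError(
                "motif residues are drawn without replacement per position; "
                f"at most {_N_AA} classes are distinguishable"
            )
        if len(self.n_per_class) != self.n_classes:
            raise ValueError("n_per_class must list one count per class")
        if not all(1 <= p <= SIGNATURE_LENGTH for p in self.motif_positions):
            raise ValueError(f"motif positions must lie in 1..{SIGNATURE_LENGTH}")
        if len(set(self.motif_positions)) != len(self.motif_positions):
            raise ValueError("motif positions must be distinct")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0, 1]")
        if self.label_names is not None and len(self.label_names) != self.n_classes:
            raise ValueError("label_names must list one name per class")

    @classmethod
    def balanced(
        cls,
        n_classes: int,
        per_class: int,
        n_motif: int = 12,
        motif_strength: float = 1.0,
        seed: int = 0,
        **kw,
    ) -> "SynthSpec":
        """Balanced dataset whose motif occupies the first ``n_motif`` positions."""
        return cls(
            n_classes=n_classes,
            n_per_class=(per_class,) * n_classes,
            motif_positions=tuple(range(1, n_motif + 1)),
            motif_strength=motif_strength,
            seed=seed,
            **kw,
        )

    def labels(self) -> tuple[str, ...]:
        if self.label_names is not None:
            return self.label_names
        return tuple(f"sub{c:02d}" for c in range(self.n_classes))


def _background(spec: SynthSpec) -> np.ndarray:
    if spec.background is None:
        return np.full(_N_AA, 1.0 / _N_AA)
    bg = np.asarray(spec.background, dtype=float)
    if bg.shape != (_N_AA,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a length-20 distribution")
    return bg


def motif_residues(spec: SynthSpec) -> dict[int, tuple[str, ...]]:
    """The class-specific residue at each motif position (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    out: dict[int, tuple[str, ...]] = {}
    for pos in spec.motif_positions:
        perm = rng.permutation(_N_AA)[: spec.n_classes]
        out[pos] = tuple(AMINO_ACIDS[i] for i in perm)
    return out


def generate(spec: SynthSpec) -> list[LabeledSignature]:
    """Sample a labeled signature dataset according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    # consume the same stream as motif_residues so both agree
    motifs: dict[int, tuple[str, ...]] = {}
    for pos in spec.motif_positions:
        perm = rng.permutation(_N_AA)[: spec.n_classes]
        motifs[pos] = tuple(AMINO_ACIDS[i] for i in perm)
    bg = _background(spec)
    labels = spec.labels()

    out: list[LabeledSignature] = []
    for c in range(spec.n_classes):
        for _ in range(spec.n_per_class[c]):
            chars = [
                AMINO_ACIDS[i]
                for i in rng.choice(_N_AA, size=SIGNATURE_LENGTH, p=bg)
            ]
            for pos in spec.motif_positions:
                if rng.random() < spec.motif_strength:
                    chars[pos - 1] = motifs[pos][c]
            out.append(LabeledSignature(Signature("".join(chars)), labels[c]))
    return out


def _min_hamming(sig: str, train: Sequence[str]) -> int:
    return min(sum(a != b for a, b in zip(sig, t)) for t in train)


def generate_bucket_probe(
    spec: SynthSpec,
    k_targets: Sequence[int],
    max_retries: int = 200,
) -> tuple[list[LabeledSignature], list[tuple[Signature, int]]]:
    """Build a train set plus test points at exact minimum Hamming distances.

    Each test signature is a copy of a training signature with exactly ``k``
    randomly chosen positions mutated to differing residues. Mutations
    prefer residues unseen at that position anywhere in the training set:
    such a position then contributes 1 to the distance against *every*
    training point, which makes even distance-34 probes constructible. To
    keep unseen residues available, the training set is drawn from a
    background restricted to 14 of the 20 residues when ``spec`` does not
    set one explicitly. Every candidate is verified by brute force against
    the whole training set (a mutation can still land closer to another
    training point); failing candidates are re-drawn up to ``max_retries``
    times. ``k = 0`` is rejected: deduplicated evaluation data never
    contains a test point identical to a training one.
    """
    if any(not 1 <= k <= SIGNATURE_LENGTH for k in k_targets):
        raise ValueError(f"k targets must lie in 1..{SIGNATURE_LENGTH}")
    if spec.background is None:
        from dataclasses import replace

        bg = np.zeros(_N_AA)
        bg[:14] = 1.0 / 14
        spec = replace(spec, background=tuple(bg))
    train = generate(spec)
    train_strs = [t.signature.residues for t in train]
    rng = np.random.default_rng(spec.seed + 1)
    used_at = [
        {t[p] for t in train_strs} for p in range(SIGNATURE_LENGTH)
    ]

    probes: list[tuple[Signature, int]] = []
    for k in k_targets:
        for _ in range(max_retries):
            base = train_strs[rng.integers(len(train_strs))]
            pos = rng.choice(SIGNATURE_LENGTH, size=k, replace=False)
            chars = list(base)
            for p in pos:
                unseen = [a for a in AMINO_ACIDS if a not in used_at[p] and a != chars[p]]
                choices = unseen or [a for a in AMINO_ACIDS if a != chars[p]]
                chars[p] = choices[rng.integers(len(choices))]
            cand = "".join(chars)
            if _min_hamming(cand, train_strs) == k:
                probes.append((Signature(cand), k))
                break
        else:
            raise RuntimeError(
                f"could not construct a probe at distance {k} after "
                f"{max_retries} attempts"
            )
    return train, probes


# ---------------------------------------------------------------------------
# Toy profile + threaded sequences for the extraction pipeline


def _consensus(n: int, rng: np.random.Generator) -> str:
    """Random consensus with no residue repeated within a 3-wide window,
    so engineered deletions have an unambiguous alignment column."""
    chars: list[str] = []
    for _ in range(n):
        forbidden = set(chars[-2:])
        choices = [a for a in AMINO_ACIDS if a not in forbidden]
        chars.append(choices[rng.integers(len(choices))])
    return "".join(chars)


def _flank(n: int, avoid: str, rng: np.random.Generator) -> str:
    out = []
    for _ in range(n):
        choices = [a for a in AMINO_ACIDS if a != avoid]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


@dataclass(frozen=True)
class ToyFixture:
    hmm_path: Path
    fasta_path: Path
    table_path: Path
    expected: dict[str, str]  # record id -> ground-truth signature


def generate_toy_profile_and_sequences(
    out_dir: str | Path,
    n_match_states: int = 50,
    positions: SignaturePositions | None = None,
    seed: int = 0,
) -> ToyFixture:
    """Write a toy HMMER3 profile, FASTA queries and their true signatures.

    The profile is built from copies of a random consensus, so match
    emissions are near-deterministic. Queries are the consensus threaded
    with known edits: flanking residues (soft-clipped by local alignment),
    an internal insertion (consumes no match state), and a deletion at one
    configured signature position (must surface as ``'-'``). Files are
    byte-identical across runs with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if positions is None:
        if n_match_states < SIGNATURE_LENGTH + 2:
            raise ValueError("toy profile needs enough match states for 34 positions")
        positions = SignaturePositions(tuple(range(2, SIGNATURE_LENGTH + 2)))
    if max(positions.positions) > n_match_states:
        raise ValueError("positions exceed the toy profile's match-state count")

    rng = np.random.default_rng(seed)
    cons = _consensus(n_match_states, rng)

    # profile from 8 identical consensus copies
    alphabet = easel.Alphabet.amino()
    seqs = [
        easel.TextSequence(name=f"train{i}".encode(), sequence=cons)
        for i in range(8)
    ]
    msa = easel.TextMSA(name=b"toy_adomain", sequences=seqs).digitize(alphabet)
    builder = plan7.Builder(alphabet, seed=7)
    hmm, _, _ = builder.build_msa(msa, plan7.Background(alphabet))
    hmm_path = out_dir / "toy.hmm"
    with open(hmm_path, "wb") as fh:
        hmm.write(fh, binary=False)

    true_sig = "".join(cons[p - 1] for p in positions.positions)

    # deletion at a configured match state near the middle of the position list
    p_del = positions.positions[len(positions.positions) // 2]
    del_seq = cons[: p_del - 1] + cons[p_del:]
    del_sig = "".join(
        "-" if p == p_del else cons[p - 1] for p in positions.positions
    )

    # internal insertion between two match states away from the deletion test
    ins_at = n_match_states // 3
    ins = _flank(3, cons[ins_at - 1], rng)
    while ins[-1] == cons[ins_at]:
        ins = _flank(3, cons[ins_at - 1], rng)
    ins_seq = cons[:ins_at] + ins + cons[ins_at:]

    records = {
        "exact": _flank(5, cons[0], rng) + cons + _flank(5, cons[-1], rng),
        "inserted": ins_seq,
        "deleted": del_seq,
    }
    expected = {"exact": true_sig, "inserted": true_sig, "deleted": del_sig}

    fasta_path = out_dir / "toy.fasta"
    with open(fasta_path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n{seq}\n")

    table_path = out_dir / "expected_signatures.tsv"
    with open(table_path, "w") as fh:
        fh.write("id\tsignature\n")
        for rid, sig in expected.items():
            fh.write(f"{rid}\t{sig}\n")

    return ToyFixture(hmm_path, fasta_path, table_path, expected)
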
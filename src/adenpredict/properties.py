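"""Substrate chemical-property prediction for novel A-domains.

A classifier over substrate identities cannot say anything useful about an
A-domain whose true substrate was never seen in training. Property-level
prediction sidesteps this: each substrate monomer maps to categorical
chemical attributes (polarity, charge, aromaticity, carboxyl / hydroxyl
groups, side-chain size, hydrophobicity class), and one classifier is
trained per attribute. A novel domain then still gets a chemical sketch of
its substrate, narrowing down its identity.

The label -> property mapping is chemistry, not learned: it ships as a
curated, user-extensible JSON table covering the proteinogenic amino acids
plus common nonribosomal monomers (ornithine, 2,3-dihydroxybenzoate, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

from .evaluation import EvaluationReport, SplitSpec, evaluate
from .signatures import LabeledSignature, Signature

#: Attribute name -> allowed categories. Binary attributes are yes/no on the
#: side chain; hydrophobicity is the three-way class used throughout.
PROPERTY_SCHEMA: dict[str, tuple[str, ...]] = {
    "polarity": ("nonpolar", "polar"),
    "charge": ("negative", "neutral", "positive"),
    "aromaticity": ("no", "yes"),
    "carboxyl": ("no", "yes"),
    "hydroxyl": ("no", "yes"),
    "side_chain_large": ("no", "yes"),
    "hydrophobicity": ("hydrophilic", "hydrophobic_aliphatic", "hydrophobic_aromatic"),
}


@dataclass(frozen=True)
class SubstratePropertyProfile:
    """Categorical chemical attributes of one substrate monomer.

    ``side_chain_large`` is yes when the side chain contains more than four
    heavy (non-hydrogen) atoms; ``charge`` follows the physiological-pH
    convention.
    """

    polarity: str
    charge: str
    aromaticity: str
    carboxyl: str
    hydroxyl: str
    side_chain_large: str
    hydrophobicity: str
    provenance: str = ""

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "provenance":
                continue
            value = getattr(self, f.name)
            allowed = PROPERTY_SCHEMA[f.name]
            if value not in allowed:
                raise ValueError(
                    f"{f.name}={value!r} not in allowed categories {allowed}"
                )
        if self.aromaticity == "yes" and self.hydrophobicity == "hydrophobic_aliphatic":
            raise ValueError(
                "inconsistent profile: aromatic monomer classed hydrophobic_aliphatic"
            )


class PropertyTable:
    """Mapping from substrate label to its chemical property profile."""

    def __init__(self, profiles: Mapping[str, SubstratePropertyProfile]):
        self._profiles = dict(profiles)

    def __contains__(self, label: str) -> bool:
        return label in self._profiles

    def __len__(self) -> int:
        return len(self._profiles)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self._profiles))

    def lookup(self, label: str) -> SubstratePropertyProfile:
        try:
            return self._profiles[label]
        except KeyError:
            raise KeyError(
                f"substrate label {label!r} not in property table; add a "
                "curated entry for this monomer"
            ) from None

    @classmethod
    def from_json(cls, path: str | Path) -> "PropertyTable":
        with open(path) as fh:
            doc = json.load(fh)
        entries = doc.get("monomers", doc)
        profiles = {
            label: SubstratePropertyProfile(**entry)
            for label, entry in entries.items()
            if isinstance(entry, dict)
        }
        return cls(profiles)

    @classmethod
    def default(cls) -> "PropertyTable":
        doc = json.loads(
            files("adenpredict.data").joinpath("substrate_properties.json").read_text()
        )
        return cls(
            {
                label: SubstratePropertyProfile(**entry)
                for label, entry in doc["monomers"].items()
            }
        )


def label_to_properties(label: str, table: PropertyTable | None = None) -> SubstratePropertyProfile:
    """Look up the curated property profile of a substrate label."""
    if table is None:
        table = PropertyTable.default()
    return table.lookup(label)


def derive_property_dataset(
    data: Sequence[LabeledSignature],
    table: PropertyTable | None = None,
    property_name: str = "hydrophobicity",
) -> list[LabeledSignature]:
    """Relabel a substrate dataset with one property's categories.

    Every input datapoint is kept; an uncovered label is an error rather
    than a silent drop, forcing explicit curation of new monomers.
    """
    if property_name not in PROPERTY_SCHEMA:
        raise ValueError(
            f"unknown property {property_name!r}; choose from "
            f"{sorted(PROPERTY_SCHEMA)}"
        )
    if table is None:
        table = PropertyTable.default()
    return [
        LabeledSignature(
            d.signature, getattr(table.lookup(d.label), property_name)
        )
        for d in data
    ]


def evaluate_property(
    dataset: Sequence[LabeledSignature],
    table: PropertyTable | None = None,
    property_name: str = "hydrophobicity",
    scheme: str = "onehot",
    backend: str = "extra_trees",
    weight_balanced: bool = False,
    split: SplitSpec | None = None,
    hyperparams: Mapping | None = None,
) -> EvaluationReport:
    """Repeated-holdout evaluation on property categories instead of labels.

    Same contract as :func:`adenpredict.evaluation.evaluate`; the report's
    per-class F1 covers the property's categories (for hydrophobicity this
    is the hydrophilic / hydrophobic-aliphatic / hydrophobic-aromatic
    breakdown).
    """
    derived = derive_property_dataset(dataset, table, property_name)
    return evaluate(
        derived,
        scheme=scheme,
        backend=backend,
        weight_balanced=weight_balanced,
        split=split,
        hyperparams=hyperparams,
    )
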
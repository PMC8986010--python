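"""Interface-derived 3D pharmacophore models.

A pharmacophore model is a set of typed, labelled tolerance spheres built
from hot-spot residues of a protein-protein interface, plus a constraint
specification (an essential label set and "at least k of this group"
choice groups).  The two canonical model shapes handled here are the
receptor-side model (2 anion + 2 aromatic + 1 hydrophobic point, with the
hydrophobic point essential) and its cytokine-side mirror (2 cation +
2 aromatic + 1 hydrophobic).

Feature centers are derived deterministically from PDB atom names:

* ``Aro`` — centroid of the side-chain aromatic ring heavy atoms,
* ``Ani`` — midpoint of the two carboxylate oxygens,
* ``Cat`` — the guanidinium carbon (Arg) or terminal amine nitrogen (Lys),
* ``Hyd`` — centroid of side-chain carbons beyond the beta carbon.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import MolecularStructure

FEATURE_TYPES = ("Aro", "Hyd", "Ani", "Cat", "Don", "Acc")

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
ANIONIC_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
CATIONIC_ANCHOR = {"ARG": "CZ", "LYS": "NZ"}
_SIDECHAIN_CARBON_PREFIXES = ("CG", "CD", "CE", "CZ", "CH")


@dataclass(frozen=True)
class PharmacophoreFeature:
    """A typed tolerance sphere; ``radius`` is the match tolerance in Å."""

    label: str
    ftype: str
    center: tuple[float, float, float]
    radius: float = 1.0
    source_residue: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, float)


@dataclass(frozen=True)
class ConstraintSpec:
    """Essential labels plus at-least-k choice groups over labels."""

    essential: frozenset[str] = frozenset()
    choice_groups: tuple[tuple[frozenset[str], int], ...] = ()

    def validate(self, labels: set[str]) -> None:
        unknown = set(self.essential) - labels
        for group, k in self.choice_groups:
            unknown |= set(group) - labels
            if not (1 <= k <= len(group)):
                raise ValueError(f"choice group {sorted(group)}: k={k} out of range")
        if unknown:
            raise ValueError(f"constraints reference unknown labels: {sorted(unknown)}")


def constraints_satisfied(constraints: ConstraintSpec, matched_labels) -> bool:
    """True iff the essential set is matched and every choice group has >= k matched members."""
    matched = set(matched_labels)
    if not set(constraints.essential) <= matched:
        return False
    return all(len(set(group) & matched) >= k for group, k in constraints.choice_groups)


@dataclass
class PharmacophoreModel:
    name: str
    features: list[PharmacophoreFeature]
    constraints: ConstraintSpec = field(default_factory=ConstraintSpec)

    def __post_init__(self) -> None:
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError("feature labels must be unique")
        self.constraints.validate(set(labels))

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def feature(self, label: str) -> PharmacophoreFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    # -- text serialization (versionable fixture format) -------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "features": [
                {
                    "label": f.label, "type": f.ftype,
                    "center": [round(c, 6) for c in f.center], "radius": f.radius,
                    "source_residue": list(f.source_residue) if f.source_residue else None,
                }
                for f in self.features
            ],
            "constraints": {
                "essential": sorted(self.constraints.essential),
                "choice_groups": [[sorted(g), k] for g, k in self.constraints.choice_groups],
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        doc = json.loads(text)
        feats = [
            PharmacophoreFeature(
                label=f["label"], ftype=f["type"], center=tuple(f["center"]), radius=f["radius"],
                source_residue=tuple(f["source_residue"]) if f.get("source_residue") else None,
            )
            for f in doc["features"]
        ]
        cons = ConstraintSpec(
            essential=frozenset(doc["constraints"]["essential"]),
            choice_groups=tuple(
                (frozenset(g), k) for g, k in doc["constraints"]["choice_groups"]
            ),
        )
        return cls(doc["name"], feats, cons)


def either_or_constraints(pairs: list[tuple[str, str]], essential: list[str]) -> ConstraintSpec:
    """Constraint shape used by both interface models: one of each pair, plus essentials."""
    return ConstraintSpec(
        essential=frozenset(essential),
        choice_groups=tuple((frozenset(p), 1) for p in pairs),
    )


# --------------------------------------------------------------------------
# feature-center derivation from residues
# --------------------------------------------------------------------------

def _residue_atom_coords(structure: MolecularStructure, chain: str, resseq: int, names) -> np.ndarray:
    idx = structure.residue_atom_indices(chain, resseq)
    by_name = {structure.atoms[i].name: structure.atoms[i].coords for i in idx}
    missing = [n for n in names if n not in by_name]
    if missing:
        resname = structure.atoms[idx[0]].residue_name
        raise ValueError(f"residue {chain}:{resseq} ({resname}) lacks side-chain atoms {missing}")
    return np.array([by_name[n] for n in names])


def feature_center(structure: MolecularStructure, chain: str, resseq: int, ftype: str) -> np.ndarray:
    """Deterministic feature anchor for a hot-spot residue of the given type."""
    idx = structure.residue_atom_indices(chain, resseq)
    resname = structure.atoms[idx[0]].residue_name
    if ftype == "Aro":
        if resname not in AROMATIC_RING_ATOMS:
            raise ValueError(f"residue {chain}:{resseq} ({resname}): no aromatic-ring rule")
        return _residue_atom_coords(structure, chain, resseq, AROMATIC_RING_ATOMS[resname]).mean(axis=0)
    if ftype == "Ani":
        if resname not in ANIONIC_ATOMS:
            raise ValueError(f"residue {chain}:{resseq} ({resname}): no anionic-group rule")
        return _residue_atom_coords(structure, chain, resseq, ANIONIC_ATOMS[resname]).mean(axis=0)
    if ftype == "Cat":
        if resname not in CATIONIC_ANCHOR:
            raise ValueError(f"residue {chain}:{resseq} ({resname}): no cationic-anchor rule")
        return _residue_atom_coords(structure, chain, resseq, (CATIONIC_ANCHOR[resname],))[0]
    if ftype == "Hyd":
        names = [
            structure.atoms[i].name for i in idx
            if structure.atoms[i].element == "C"
            and structure.atoms[i].name.startswith(_SIDECHAIN_CARBON_PREFIXES)
        ]
        if not names:
            raise ValueError(f"residue {chain}:{resseq} ({resname}): no side-chain carbons beyond CB")
        return _residue_atom_coords(structure, chain, resseq, names).mean(axis=0)
    raise ValueError(f"no center-derivation rule for feature type {ftype!r}")


def build_interface_model(
    structure: MolecularStructure,
    hotspots: list[tuple[str, int, str]],
    name: str,
    default_radius: float = 1.0,
) -> PharmacophoreModel:
    """One feature per hot-spot residue, labelled F1..Fn in input order.

    Constraints are left empty; callers attach the model's constraint rule
    (see :func:`either_or_constraints`) afterwards.
    """
    feats = []
    for k, (chain, resseq, ftype) in enumerate(hotspots, start=1):
        center = feature_center(structure, chain, resseq, ftype)
        resname = structure.residue_name(chain, resseq)
        feats.append(
            PharmacophoreFeature(
                label=f"F{k}", ftype=ftype, center=tuple(float(c) for c in center),
                radius=default_radius, source_residue=(chain, resseq, resname),
            )
        )
    return PharmacophoreModel(name, feats)


# --------------------------------------------------------------------------
# hot-spot interaction-class mapping
# --------------------------------------------------------------------------

_ACIDIC = {"GLU", "ASP", "GLUTAMATE", "ASPARTATE"}
_BASIC = {"ARG", "LYS", "ARGININE", "LYSINE"}

INTERACTION_CLASSES = ("aromatic_ring", "hydrophobic", "salt_bridge")


@dataclass(frozen=True)
class HotspotMappingRule:
    """How one interface interaction class maps partner residues to feature types."""

    interaction_class: str

    def ftype_for(self, partner_residue_chemistry: str) -> str:
        return complementary_ftype(self.interaction_class, partner_residue_chemistry)


INTERFACE_CONTACT_RULES = tuple(HotspotMappingRule(c) for c in INTERACTION_CLASSES)


def complementary_ftype(interaction_class: str, partner_residue_chemistry: str) -> str:
    """Feature type contributed by a residue under an interface interaction class.

    Aromatic-ring partners give ``Aro``, hydrophobic give ``Hyd``; for a
    salt bridge an acidic residue contributes an anion point and a basic
    residue a cation point.
    """
    if interaction_class == "aromatic_ring":
        return "Aro"
    if interaction_class == "hydrophobic":
        return "Hyd"
    if interaction_class == "salt_bridge":
        chem = partner_residue_chemistry.upper()
        if chem in _ACIDIC or chem == "ACIDIC":
            return "Ani"
        if chem in _BASIC or chem == "BASIC":
            return "Cat"
        raise ValueError(f"salt_bridge: cannot type residue chemistry {partner_residue_chemistry!r}")
    raise ValueError(f"unmapped interaction class {interaction_class!r}")
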
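"""Ligand-side feature perception, geometric pharmacophore matching and drug-likeness.

Feature perception is rule-based and deterministic: aromatic rings are
smallest-ring-basis rings whose atoms are all unsaturated, cationic
centers are charged/protonatable nitrogens, anionic centers are
carboxylate/sulfonate/phosphate/nitro oxygen groups (one anchor per
group), hydrophobic centers are connected clusters of >= 3 carbons with
no bonded heteroatom, and donors/acceptors are N/O with hydrogens/lone
pairs.  Matching enumerates injective, type-compatible assignments of
ligand features to model labels (>= 3 points, constraints satisfied),
superposes the assigned positions onto the model centers with the Kabsch
algorithm and accepts when every assigned feature lands inside its model
sphere.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import SmallMolecule
from .pharmacophore import ConstraintSpec, PharmacophoreModel, constraints_satisfied
from .trajectory import kabsch_superpose

MIN_MATCH_POINTS = 3  # a 3-point superposition is the smallest well-determined fit

_HETERO = lambda el: el not in ("C", "H")

_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3, "H": 1}


@dataclass(frozen=True)
class LigandFeature:
    ftype: str
    position: tuple[float, float, float]
    member_atoms: frozenset[int]

    @property
    def position_array(self) -> np.ndarray:
        return np.asarray(self.position, float)


@dataclass
class MatchResult:
    conformer: int
    assignment: dict[str, LigandFeature]
    fit_rmsd: float
    satisfied: bool

    def sort_key(self):
        return (self.fit_rmsd, tuple(sorted((lab, f.member_atoms) for lab, f in
                                            ((k, v) for k, v in self.assignment.items()))))


# --------------------------------------------------------------------------
# perception helpers
# --------------------------------------------------------------------------

def _bond_graph(mol: SmallMolecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    for i, j, o in mol.bonds:
        g.add_edge(i, j, order=o)
    return g


def _valence_sum(mol: SmallMolecule, i: int) -> float:
    return sum(o for _, o in mol.neighbors(i))


def implicit_hydrogens(mol: SmallMolecule, i: int) -> int:
    """Implicit hydrogen count from standard valences, adjusted for formal charge."""
    el = mol.elements[i]
    if el not in _DEFAULT_VALENCE:
        return 0
    valence = _DEFAULT_VALENCE[el]
    if el in ("N", "O", "S", "P"):
        valence += mol.formal_charges[i]
    explicit = _valence_sum(mol, i)
    return max(0, int(round(valence - explicit)))


def hydrogen_count(mol: SmallMolecule, i: int) -> int:
    """Total hydrogens on atom i: explicit H neighbours plus implicit ones."""
    explicit_h = sum(1 for j, _ in mol.neighbors(i) if mol.elements[j] == "H")
    if explicit_h:
        return explicit_h
    return implicit_hydrogens(mol, i)


def _aromatic_rings(mol: SmallMolecule, g: nx.Graph) -> list[list[int]]:
    """Rings of a smallest-ring basis in which every atom carries unsaturation."""
    rings = []
    for ring in nx.minimum_cycle_basis(g):
        ok = len(ring) >= 5
        for i in ring:
            if mol.elements[i] == "H":
                ok = False
                break
            if not any(o >= 1.5 for _, o in mol.neighbors(i)):
                ok = False
                break
        if ok:
            rings.append(sorted(ring))
    return rings


def _anionic_groups(mol: SmallMolecule) -> list[tuple[list[int], list[int]]]:
    """(all member atoms, anchor oxygens) per acidic group; anchor is the O centroid."""
    groups = []
    for i, el in enumerate(mol.elements):
        if el not in ("C", "S", "P", "N"):
            continue
        term_o = [j for j, _ in mol.neighbors(i)
                  if mol.elements[j] == "O" and len(mol.neighbors(j)) == 1]
        if el == "C" and len(term_o) == 2:
            has_charge = any(mol.formal_charges[j] < 0 for j in term_o)
            has_double = any(o == 2 for j, o in mol.neighbors(i) if j in term_o)
            if has_charge or has_double:
                groups.append(([i] + term_o, term_o))
        elif el == "S" and len(term_o) >= 3:
            groups.append(([i] + term_o, term_o))
        elif el == "P" and len(term_o) >= 2:
            groups.append(([i] + term_o, term_o))
        elif el == "N" and len(term_o) == 2:
            # nitro: one anchor at the O-O midpoint
            groups.append(([i] + term_o, term_o))
    return groups


def _guanidinium_carbons(mol: SmallMolecule) -> list[int]:
    out = []
    for i, el in enumerate(mol.elements):
        if el != "C":
            continue
        n_nbrs = [(j, o) for j, o in mol.neighbors(i) if mol.elements[j] == "N"]
        if len(n_nbrs) == 3 and (any(o == 2 for _, o in n_nbrs)
                                 or any(mol.formal_charges[j] > 0 for j, _ in n_nbrs)):
            out.append(i)
    return out


def perceive_features(mol: SmallMolecule, conformer: int = 0) -> list[LigandFeature]:
    """Perceive typed interaction features on one conformer of a molecule."""
    if not (0 <= conformer < len(mol.conformers)):
        raise IndexError(f"conformer {conformer} out of range (molecule has {len(mol.conformers)})")
    coords = mol.conformers[conformer]
    g = _bond_graph(mol)
    feats: list[LigandFeature] = []

    rings = _aromatic_rings(mol, g)
    ring_atoms = set(itertools.chain.from_iterable(rings))
    for ring in rings:
        feats.append(LigandFeature("Aro", tuple(coords[ring].mean(axis=0)), frozenset(ring)))

    ani_groups = _anionic_groups(mol)
    ani_members = set(itertools.chain.from_iterable(m for m, _ in ani_groups))
    for members, anchor_o in ani_groups:
        feats.append(LigandFeature("Ani", tuple(coords[anchor_o].mean(axis=0)), frozenset(members)))

    guanidinium = _guanidinium_carbons(mol)
    guan_n = {j for i in guanidinium for j, _ in mol.neighbors(i) if mol.elements[j] == "N"}
    for i in guanidinium:
        members = frozenset([i]) | frozenset(j for j, _ in mol.neighbors(i) if mol.elements[j] == "N")
        feats.append(LigandFeature("Cat", tuple(coords[i]), members))
    for i, el in enumerate(mol.elements):
        if el != "N" or i in guan_n or i in ani_members:
            continue
        heavy_nbrs = [(j, o) for j, o in mol.neighbors(i) if mol.elements[j] != "H"]
        total_conn = len(heavy_nbrs) + hydrogen_count(mol, i)
        quaternary = total_conn >= 4 and mol.formal_charges[i] > 0
        if quaternary:
            feats.append(LigandFeature("Cat", tuple(coords[i]), frozenset([i])))
            continue
        aliphatic = (
            all(o == 1 for _, o in heavy_nbrs)
            and all(mol.elements[j] == "C" for j, _ in heavy_nbrs)
            and not any(j in ring_atoms for j, _ in heavy_nbrs)
            and not any(any(mol.elements[k] == "O" and o2 == 2 for k, o2 in mol.neighbors(j))
                        for j, _ in heavy_nbrs)
        )
        if aliphatic and (mol.formal_charges[i] > 0 or hydrogen_count(mol, i) >= 1):
            feats.append(LigandFeature("Cat", tuple(coords[i]), frozenset([i])))

    carbon_g = g.subgraph([
        i for i, el in enumerate(mol.elements)
        if el == "C" and i not in ring_atoms
        and not any(_HETERO(mol.elements[j]) for j, _ in mol.neighbors(i))
    ])
    for comp in nx.connected_components(carbon_g):
        if len(comp) >= 3:
            members = sorted(comp)
            feats.append(LigandFeature("Hyd", tuple(coords[members].mean(axis=0)), frozenset(members)))

    for i, el in enumerate(mol.elements):
        if el not in ("N", "O"):
            continue
        if hydrogen_count(mol, i) >= 1:
            feats.append(LigandFeature("Don", tuple(coords[i]), frozenset([i])))
        if el == "O":
            feats.append(LigandFeature("Acc", tuple(coords[i]), frozenset([i])))
        else:
            total = _valence_sum(mol, i) + implicit_hydrogens(mol, i)
            if total < 4:  # quaternary/charged-saturated N has no lone pair
                feats.append(LigandFeature("Acc", tuple(coords[i]), frozenset([i])))
    return feats


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

def _assignments(labels: list[str], candidates: dict[str, list[int]]):
    """All injective assignments label -> feature index, labels in fixed order."""
    def rec(k: int, used: set[int], acc: list[int]):
        if k == len(labels):
            yield list(acc)
            return
        for fi in candidates[labels[k]]:
            if fi in used:
                continue
            used.add(fi)
            acc.append(fi)
            yield from rec(k + 1, used, acc)
            acc.pop()
            used.discard(fi)
    yield from rec(0, set(), [])


def match_model(
    model: PharmacophoreModel,
    features: list[LigandFeature],
    conformer: int = 0,
    min_points: int = MIN_MATCH_POINTS,
) -> list[MatchResult]:
    """All accepted placements of a feature set onto a pharmacophore model.

    For every label subset of size >= ``min_points`` that satisfies the
    model constraints and every injective type-compatible assignment of
    ligand features to those labels, the assigned positions are rigidly
    superposed onto the model centers; the assignment is accepted iff
    every feature then lies within its label's tolerance sphere.  Results
    are sorted by fit RMSD (ties broken lexicographically by assignment).
    """
    if not model.features:
        raise ValueError("model has no features")
    candidates = {
        f.label: [i for i, lf in enumerate(features) if lf.ftype == f.ftype]
        for f in model.features
    }
    results: list[MatchResult] = []
    labels = model.labels
    for size in range(min_points, len(labels) + 1):
        for subset in itertools.combinations(labels, size):
            if not constraints_satisfied(model.constraints, set(subset)):
                continue
            sub = list(subset)
            centers = np.array([model.feature(lab).center for lab in sub])
            radii = np.array([model.feature(lab).radius for lab in sub])
            for assign in _assignments(sub, candidates):
                pos = np.array([features[fi].position for fi in assign])
                try:
                    sup = kabsch_superpose(centers, pos)
                except ValueError:
                    continue  # geometrically degenerate placement
                moved = sup.apply(pos)
                dist = np.linalg.norm(moved - centers, axis=1)
                if np.all(dist <= radii + 1e-9):
                    results.append(MatchResult(
                        conformer=conformer,
                        assignment={lab: features[fi] for lab, fi in zip(sub, assign)},
                        fit_rmsd=sup.rmsd, satisfied=True,
                    ))
    results.sort(key=lambda m: (round(m.fit_rmsd, 9),
                                tuple(sorted((lab, tuple(sorted(f.member_atoms)))
                                             for lab, f in m.assignment.items()))))
    return results


def match_conformers(model: PharmacophoreModel, mol: SmallMolecule, **kw) -> list[MatchResult]:
    out = []
    for ci in range(len(mol.conformers)):
        out.extend(match_model(model, perceive_features(mol, ci), conformer=ci, **kw))
    return out


# --------------------------------------------------------------------------
# drug-likeness
# --------------------------------------------------------------------------

@dataclass
class LipinskiReport:
    mw: float
    logp: float
    hba: int
    hbd: int
    passes: bool
    violated_rules: list[str]


def _to_rdkit(mol: SmallMolecule, conformer: int = 0):
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401  (registers conformer code)
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for el, q in zip(mol.elements, mol.formal_charges):
        a = Chem.Atom(el)
        a.SetFormalCharge(int(q))
        rw.AddAtom(a)
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for i, j, o in mol.bonds:
        rw.AddBond(int(i), int(j), order_map.get(o, Chem.BondType.SINGLE))
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    if mol.conformers:
        conf = Chem.Conformer(m.GetNumAtoms())
        for i, (x, y, z) in enumerate(mol.conformers[conformer]):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        m.AddConformer(conf)
    return m


def molecular_weight(mol: SmallMolecule) -> float:
    """Average molecular weight from standard atomic weights, implicit H included."""
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    mw = 0.0
    h_weight = pt.GetAtomicWeight("H")
    for i, el in enumerate(mol.elements):
        try:
            mw += pt.GetAtomicWeight(el)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"unknown element {el!r}") from exc
        if el != "H":
            mw += h_weight * implicit_hydrogens(mol, i)
    return mw


def estimate_logp(mol: SmallMolecule) -> float:
    """Wildman-Crippen atom-contribution logP (used when no precomputed value exists)."""
    from rdkit.Chem import Crippen

    try:
        m = _to_rdkit(mol)
    except Exception as exc:
        raise ValueError("cannot build a sanitized molecule for logP estimation") from exc
    return float(Crippen.MolLogP(m, includeHs=True))


def lipinski_filter(mol: SmallMolecule) -> LipinskiReport:
    """Rule-of-five report: MW < 500 Da, logP < 5, HBA (N+O) <= 10, HBD (N-H/O-H) <= 5."""
    unknown = [el for el in mol.elements if el not in _DEFAULT_VALENCE and el not in
               ("He", "Li", "Be", "Na", "Mg", "Si", "K", "Ca", "Se")]
    if unknown:
        raise ValueError(f"unknown elements for drug-likeness evaluation: {sorted(set(unknown))}")
    mw = molecular_weight(mol)
    hba = sum(1 for el in mol.elements if el in ("N", "O"))
    hbd = sum(hydrogen_count(mol, i) for i, el in enumerate(mol.elements) if el in ("N", "O"))
    if "logP" in mol.properties:
        logp = float(mol.properties["logP"])
    else:
        logp = estimate_logp(mol)
    violated = []
    if not mw < 500.0:
        violated.append("MW")
    if not logp < 5.0:
        violated.append("logP")
    if not hba <= 10:
        violated.append("HBA")
    if not hbd <= 5:
        violated.append("HBD")
    return LipinskiReport(mw=mw, logp=logp, hba=hba, hbd=hbd,
                          passes=not violated, violated_rules=violated)
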
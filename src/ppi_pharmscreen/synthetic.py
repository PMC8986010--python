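"""Synthetic study inputs: toy interfaces, probe ligands, scheduled trajectories.

Every stage of the pipeline can be exercised without external downloads:

* :func:`make_toy_interface` builds a two-chain complex whose hot-spot
  residues realise the three interface interaction classes (aromatic
  ring, hydrophobic, salt bridge) within the detector cutoffs,
* :func:`make_matching_ligand` builds multi-fragment probe molecules
  whose perceived features sit exactly on a pharmacophore model's
  centers (and decoys missing an essential feature),
* :func:`make_trajectory` poses a probe ligand against the receptor
  chain frame by frame according to a contact schedule, so the expected
  occupancy of every scheduled contact is known by construction,
* :func:`assign_toy_forcefield` draws physically plausible charges and
  LJ/GB parameters for energy tests.

All generators are deterministic functions of their seed.  Residues use
real amino-acid atom names (minimal backbone N/H/CA/C/O) so feature
derivation and the contact detectors run unmodified.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, MolecularStructure, SmallMolecule, TrajectoryEnsemble
from .mmgbsa import ForceFieldParams
from .pharmacophore import PharmacophoreModel, constraints_satisfied
from .trajectory import (
    HBOND_MAX_DA, HBOND_MIN_ANGLE, SALT_BRIDGE_CUTOFF, HYDROPHOBIC_CUTOFF,
    AROMATIC_CENTROID_CUTOFF, InteractionGroups, ChargedGroup, hbond_angle,
)

DEFAULT_SEED = 20220406  # anchors the fixture suite

# --------------------------------------------------------------------------
# residue templates (local frame: CA at origin, side chain toward +x)
# --------------------------------------------------------------------------

_BACKBONE = [
    ("N", "N", (-1.46, 0.0, 0.0)),
    ("H", "H", (-1.95, 0.95, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (0.70, -1.25, 0.0)),
    ("O", "O", (1.92, -1.30, 0.10)),
]

_PHE_RING = [
    ("CG", "C", (2.21, 1.30, 0.0)),
    ("CD1", "C", (2.905, 2.5037, 0.0)),
    ("CD2", "C", (2.905, 0.0963, 0.0)),
    ("CE1", "C", (4.295, 2.5037, 0.0)),
    ("CE2", "C", (4.295, 0.0963, 0.0)),
    ("CZ", "C", (4.99, 1.30, 0.0)),
]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "PHE": _BACKBONE + [("CB", "C", (0.70, 1.30, 0.0))] + _PHE_RING,
    "TYR": _BACKBONE + [("CB", "C", (0.70, 1.30, 0.0))] + _PHE_RING
    + [("OH", "O", (6.35, 1.30, 0.0)), ("HH", "H", (6.85, 2.05, 0.0))],
    "GLU": _BACKBONE + [
        ("CB", "C", (0.70, 1.30, 0.0)), ("CG", "C", (2.20, 1.30, 0.0)),
        ("CD", "C", (3.70, 1.30, 0.0)),
        ("OE1", "O", (4.35, 2.35, 0.0)), ("OE2", "O", (4.35, 0.25, 0.0)),
    ],
    "ARG": _BACKBONE + [
        ("CB", "C", (0.70, 1.30, 0.0)), ("CG", "C", (2.20, 1.30, 0.0)),
        ("CD", "C", (3.70, 1.30, 0.0)), ("NE", "N", (5.10, 1.30, 0.0)),
        ("HE", "H", (5.40, 2.25, 0.0)), ("CZ", "C", (6.40, 1.30, 0.0)),
        ("NH1", "N", (7.05, 2.40, 0.0)), ("NH2", "N", (7.05, 0.20, 0.0)),
        ("HH11", "H", (6.60, 3.20, 0.0)), ("HH12", "H", (8.00, 2.50, 0.0)),
        ("HH21", "H", (6.60, -0.60, 0.0)), ("HH22", "H", (8.00, 0.10, 0.0)),
    ],
    "LEU": _BACKBONE + [
        ("CB", "C", (0.70, 1.30, 0.0)), ("CG", "C", (2.20, 1.30, 0.0)),
        ("CD1", "C", (2.90, 2.55, 0.30)), ("CD2", "C", (2.90, 0.05, -0.30)),
    ],
}

_RESIDUE_FORMAL_CHARGE = {"GLU": -1, "ASP": -1, "ARG": 1, "LYS": 1}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _residue_atoms(resname, chain, resseq, offset, mirror_x=None, serial0=1, jitter=None):
    atoms = []
    for k, (name, element, local) in enumerate(RESIDUE_TEMPLATES[resname]):
        pos = np.array(local, float)
        if mirror_x is not None:
            pos[0] = mirror_x - pos[0]
        pos = pos + np.asarray(offset, float)
        if jitter is not None:
            pos = pos + jitter[k]
        atoms.append(AtomRecord(serial=serial0 + k, name=name, element=element,
                                residue_name=resname, residue_seq=resseq, chain_id=chain,
                                coords=pos,
                                formal_charge=0))
    return atoms


# --------------------------------------------------------------------------
# toy interface
# --------------------------------------------------------------------------

_INTERFACE_ROWS = [
    # (receptor resname/resseq, partner resname/resseq, interaction class, target distance)
    (("GLU", 277), ("ARG", 179), "salt_bridge", 3.2),
    (("GLU", 278), ("ARG", 182), "salt_bridge", 3.2),
    (("PHE", 229), ("PHE", 78), "aromatic", 4.6),
    (("TYR", 230), ("PHE", 74), "aromatic", 4.6),
    (("PHE", 279), ("LEU", 178), "hydrophobic", 3.9),
]
_ROW_SPACING = 9.0

_PAIR_METRIC_ATOMS = {
    "salt_bridge": {"GLU": ("OE1", "OE2"), "ARG": ("NE", "NH1", "NH2")},
    "aromatic": {"PHE": tuple(n for n, _, _ in _PHE_RING), "TYR": tuple(n for n, _, _ in _PHE_RING)},
    "hydrophobic": {"PHE": tuple(n for n, _, _ in _PHE_RING) + ("CB",),
                    "LEU": ("CG", "CD1", "CD2")},
}


def _pair_metric(cls, r_coords, l_coords):
    if cls == "aromatic":
        return float(np.linalg.norm(r_coords.mean(axis=0) - l_coords.mean(axis=0)))
    d = np.linalg.norm(r_coords[:, None, :] - l_coords[None, :, :], axis=2)
    return float(d.min())


def make_toy_interface(seed: int = DEFAULT_SEED) -> tuple[MolecularStructure, dict]:
    """Two-chain interface realising the three interface interaction classes.

    Chain R carries the receptor-side hot spots (Glu277, Glu278, Phe229,
    Tyr230, Phe279), chain L the cytokine-side partners (Arg179, Arg182,
    Phe78, Phe74, Leu178); each partner pair sits inside its contact
    detector's cutoff.  Returns the structure and the two hot-spot lists
    (keys ``receptor`` and ``cytokine``) ready for model building.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1
    for row, ((r_name, r_seq), (l_name, l_seq), cls, target) in enumerate(_INTERFACE_ROWS):
        offset = np.array([0.0, _ROW_SPACING * row, 0.0])
        r_jit = rng.normal(scale=0.03, size=(len(RESIDUE_TEMPLATES[r_name]), 3))
        l_jit = rng.normal(scale=0.03, size=(len(RESIDUE_TEMPLATES[l_name]), 3))
        r_atoms = _residue_atoms(r_name, "R", r_seq, offset, serial0=serial, jitter=r_jit)
        serial += len(r_atoms)

        metric_r = _PAIR_METRIC_ATOMS[cls][r_name]
        metric_l = _PAIR_METRIC_ATOMS[cls][l_name]
        r_coords = np.array([a.coords for a in r_atoms if a.name in metric_r])

        def metric_at(T: float) -> float:
            l_atoms = _residue_atoms(l_name, "L", l_seq, offset, mirror_x=T, jitter=l_jit)
            l_coords = np.array([a.coords for a in l_atoms if a.name in metric_l])
            return _pair_metric(cls, r_coords, l_coords)

        lo, hi = 2.0, 60.0
        for _ in range(60):  # bisection: metric is increasing in the partner offset
            mid = 0.5 * (lo + hi)
            if metric_at(mid) < target:
                lo = mid
            else:
                hi = mid
        T = 0.5 * (lo + hi)
        l_atoms = _residue_atoms(l_name, "L", l_seq, offset, mirror_x=T, serial0=serial, jitter=l_jit)
        serial += len(l_atoms)
        atoms.extend(r_atoms)
        atoms.extend(l_atoms)

    # random global rigid motion (seeded): analyses must be frame-invariant
    R = _random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    for a in atoms:
        a.coords = R @ a.coords + t

    hotspots = {
        "receptor": [("R", 277, "Ani"), ("R", 278, "Ani"),
                     ("R", 229, "Aro"), ("R", 230, "Aro"), ("R", 279, "Hyd")],
        "cytokine": [("L", 74, "Aro"), ("L", 78, "Aro"),
                     ("L", 179, "Cat"), ("L", 182, "Cat"), ("L", 178, "Hyd")],
    }
    return MolecularStructure(atoms), hotspots


# --------------------------------------------------------------------------
# probe ligands for pharmacophore matching
# --------------------------------------------------------------------------

# fragments: (elements, formal charges, bonds, local coordinates); the
# perceived feature anchor of each fragment sits at the local origin
_FRAGMENTS = {
    "Aro": (
        ["C"] * 6, [0] * 6,
        [(0, 1, 2.0), (1, 2, 1.0), (2, 3, 2.0), (3, 4, 1.0), (4, 5, 2.0), (5, 0, 1.0)],
        [(1.3905 * math.cos(a), 1.3905 * math.sin(a), 0.0)
         for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)],
    ),
    "Hyd": (
        ["C"] * 3, [0] * 3,
        [(0, 1, 1.0), (1, 2, 1.0)],
        [(-0.75, -0.44, 0.0), (0.0, 0.88, 0.0), (0.75, -0.44, 0.0)],
    ),
    "Ani": (  # acetate; anchor = carboxylate O midpoint
        ["C", "C", "O", "O"], [0, 0, 0, -1],
        [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0)],
        [(-2.39, 0.0, 0.0), (-0.85, 0.0, 0.0), (0.0, 1.05, 0.0), (0.0, -1.05, 0.0)],
    ),
    "Cat": (  # methylammonium; anchor = N
        ["N", "H", "H", "H", "C"], [1, 0, 0, 0, 0],
        [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0)],
        [(0.0, 0.0, 0.0), (0.5, 0.8, 0.2), (0.5, -0.8, 0.2), (-0.5, 0.0, -0.9), (-1.0, 0.6, 0.8)],
    ),
    "Don": (  # methanol; anchor = O
        ["O", "H", "C"], [0, 0, 0],
        [(0, 1, 1.0), (0, 2, 1.0)],
        [(0.0, 0.0, 0.0), (0.72, 0.62, 0.0), (-1.43, 0.0, 0.0)],
    ),
    "Acc": (  # formaldehyde; anchor = O
        ["O", "C"], [0, 0],
        [(0, 1, 2.0)],
        [(0.0, 0.0, 0.0), (1.22, 0.0, 0.0)],
    ),
}


def make_matching_ligand(
    model: PharmacophoreModel,
    subset,
    seed: int = DEFAULT_SEED,
    drop=(),
    retype: dict | None = None,
) -> SmallMolecule:
    """Multi-fragment probe molecule matching a label subset of a model.

    One chemical fragment per requested label, oriented randomly (seeded)
    about an anchor placed exactly on the label's feature center, so the
    perceived feature positions coincide with the model centers.  Decoys
    are produced by dropping (``drop``) or re-typing (``retype``) labels —
    dropping an essential feature guarantees a non-match.
    """
    subset = list(subset)
    if not constraints_satisfied(model.constraints, set(subset)):
        raise ValueError(f"label subset {sorted(subset)} violates the model constraints")
    rng = np.random.default_rng(seed)
    retype = retype or {}
    elements: list[str] = []
    charges: list[int] = []
    bonds: list[tuple[int, int, float]] = []
    coords: list[np.ndarray] = []
    for label in subset:
        if label in drop:
            continue
        ftype = retype.get(label, model.feature(label).ftype)
        f_el, f_q, f_bonds, f_xyz = _FRAGMENTS[ftype]
        rot = _random_rotation(rng)
        base = len(elements)
        center = model.feature(label).center_array
        elements.extend(f_el)
        charges.extend(f_q)
        bonds.extend((base + i, base + j, o) for i, j, o in f_bonds)
        coords.extend(center + rot @ np.asarray(p, float) for p in f_xyz)
    name = f"probe-{model.name}-" + "+".join(sorted(set(subset) - set(drop)))
    return SmallMolecule(elements, charges, bonds, [np.array(coords)], name=name)


# --------------------------------------------------------------------------
# contact schedules and trajectories
# --------------------------------------------------------------------------

@dataclass
class ScheduleEntry:
    """One planted contact: class, protein residue, ligand group, presence law."""

    contact_class: str  # hbond | salt_bridge | hydrophobic | aromatic
    residue: tuple[str, int]  # (chain, resseq) on the protein side
    ligand_atoms: tuple[int, ...]  # complex atom indices of the dedicated ligand group
    p: float
    mode: str = "deterministic"  # deterministic fraction | bernoulli
    multiplicity: int = 1
    role: str = "ligand_donor"  # hbond only: ligand_donor | protein_donor

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("presence fraction p must be in [0, 1]")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.contact_class != "hbond" and self.multiplicity != 1:
            raise ValueError("multiplicity > 1 is only realisable for hydrogen bonds")


@dataclass
class ContactSchedule:
    entries: list[ScheduleEntry]
    n_frames: int
    jitter_sigma: float = 0.1
    seed: int = DEFAULT_SEED
    metadata: dict = field(default_factory=dict)

    def presence(self, rng: np.random.Generator) -> np.ndarray:
        """(n_entries, n_frames) boolean presence matrix; deterministic entries first frames."""
        out = np.zeros((len(self.entries), self.n_frames), dtype=bool)
        for e_i, e in enumerate(self.entries):
            if e.mode == "deterministic":
                k = int(round(e.p * self.n_frames))
                out[e_i, :k] = True
            elif e.mode == "bernoulli":
                out[e_i] = rng.random(self.n_frames) < e.p
            else:
                raise ValueError(f"unknown schedule mode {e.mode!r}")
        return out

    def expected_pair_occupancy(self, index: int) -> float | None:
        """Exact expected occupancy (%) for deterministic entries, None for Bernoulli."""
        e = self.entries[index]
        if e.mode != "deterministic":
            return None
        k = int(round(e.p * self.n_frames))
        return 100.0 * e.multiplicity * k / self.n_frames


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    w = ref - np.dot(ref, v) * v
    n = np.linalg.norm(w)
    if n < 1e-8:
        w = np.cross(v, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(v, np.array([0.0, 1.0, 0.0]))
        n = np.linalg.norm(w)
    return w / n


class InfeasibleSchedule(ValueError):
    pass


def _entry_poses(topology: MolecularStructure, entry: ScheduleEntry, protein_centroid: np.ndarray):
    """(present, absent) coordinate arrays for the entry's ligand group atoms."""
    chain, resseq = entry.residue
    res_idx = topology.residue_atom_indices(chain, resseq)
    by_name = {topology.atoms[i].name: topology.atoms[i].coords for i in res_idx}
    resname = topology.atoms[res_idx[0]].residue_name
    n_lig = len(entry.ligand_atoms)

    if entry.contact_class == "hbond":
        acceptors = [by_name[n] for n in ("OE1", "OE2") if n in by_name] or [by_name["O"]]
        if entry.role == "ligand_donor":
            a1 = acceptors[0]
            out = _unit(a1 - protein_centroid)
            if len(acceptors) > 1:
                # outward along the carboxylate bisector, independent of where
                # the residue sits relative to the protein centroid
                mid = 0.5 * (acceptors[0] + acceptors[1])
                axis = _unit(acceptors[0] - acceptors[1])
                w = _perp(axis, _unit(mid - by_name["CD"]))
                if np.dot(w, mid - by_name["CD"]) < 0:
                    w = -w
            if entry.multiplicity == 1 or len(acceptors) == 1:
                if len(acceptors) > 1:
                    u = _unit(w + 0.9 * axis)  # lean away from the second oxygen
                else:
                    u = out
                d_pos = a1 + 2.9 * u
            else:  # bidentate: donor on the bisector of the two acceptor oxygens
                u = w
                d_pos = mid + 2.6 * u
            h_pos = d_pos - 1.0 * u
            present = np.array([d_pos, h_pos])
            absent = np.array([d_pos + 9.0 * u, h_pos + 9.0 * u])
        else:  # protein donor -> ligand acceptor
            d_name, h_name = ("N", "H")
            d, h = by_name[d_name], by_name[h_name]
            u = _unit(h - d)
            a_pos = h + 1.9 * u
            present = np.array([a_pos])
            absent = np.array([a_pos + 9.0 * u])
        if len(present) != n_lig:
            raise InfeasibleSchedule(f"hbond entry needs {len(present)} ligand atoms, got {n_lig}")
        return present, absent

    if entry.contact_class == "salt_bridge":
        if "OE1" not in by_name or "OE2" not in by_name:
            raise InfeasibleSchedule(f"no charged-group template for residue {resname}")
        oe1, oe2 = by_name["OE1"], by_name["OE2"]
        mid = 0.5 * (oe1 + oe2)
        # approach along the carboxylate bisector so the ion sits 3.2 Å from
        # both oxygens instead of colliding with one of them
        u = _perp(_unit(oe1 - oe2), _unit(mid - by_name["CD"]))
        if np.dot(u, mid - by_name["CD"]) < 0:
            u = -u
        half = 0.5 * float(np.linalg.norm(oe1 - oe2))
        d = math.sqrt(max(3.2 ** 2 - half ** 2, 1.0))
        present = np.array([mid + d * u])
        absent = np.array([mid + (d + 10.0) * u])
        if n_lig != 1:
            raise InfeasibleSchedule("salt-bridge entries use a single-atom ligand group")
        return present, absent

    if entry.contact_class == "hydrophobic":
        names = _PAIR_METRIC_ATOMS["hydrophobic"].get(resname)
        if names is None:
            raise InfeasibleSchedule(f"no hydrophobic template for residue {resname}")
        carbons = np.array([by_name[n] for n in names if n in by_name])
        u = _unit(carbons.mean(axis=0) - protein_centroid)
        anchor = carbons[np.argmax(carbons @ u)]
        present = np.array([anchor + (3.9 + 1.52 * k) * u for k in range(n_lig)])
        absent = present + 10.0 * u
        return present, absent

    if entry.contact_class == "aromatic":
        names = _PAIR_METRIC_ATOMS["aromatic"].get(resname)
        if names is None:
            raise InfeasibleSchedule(f"no aromatic-ring template for residue {resname}")
        ring = np.array([by_name[n] for n in names])
        center = ring.mean(axis=0)
        u = _unit(center - protein_centroid)
        v = _perp(u, ring[0] - center)
        w = np.cross(u, v)
        lig_center = center + 4.6 * u
        angles = np.linspace(0, 2 * math.pi, n_lig, endpoint=False)
        present = np.array([lig_center + 1.3905 * (math.cos(a) * v + math.sin(a) * w) for a in angles])
        absent = present + 10.0 * u
        return present, absent

    raise InfeasibleSchedule(f"unknown contact class {entry.contact_class!r}")


def _verify_entry(coords, topology, entry: ScheduleEntry, present: bool) -> bool:
    """Check the scheduled contact state against the geometric criteria."""
    chain, resseq = entry.residue
    res_idx = topology.residue_atom_indices(chain, resseq)
    by_name = {topology.atoms[i].name: i for i in res_idx}
    lig = list(entry.ligand_atoms)
    if entry.contact_class == "hbond":
        if entry.role == "ligand_donor":
            d_i, h_i = lig[0], lig[1]
            acc = [by_name[n] for n in ("OE1", "OE2", "O") if n in by_name]
            count = 0
            for a_i in acc:
                r = np.linalg.norm(coords[d_i] - coords[a_i])
                if r < HBOND_MAX_DA and hbond_angle(coords[d_i], coords[h_i], coords[a_i]) > HBOND_MIN_ANGLE:
                    count += 1
            return count == (entry.multiplicity if present else 0)
        d_i, h_i = by_name["N"], by_name["H"]
        a_i = lig[0]
        r = np.linalg.norm(coords[d_i] - coords[a_i])
        hit = r < HBOND_MAX_DA and hbond_angle(coords[d_i], coords[h_i], coords[a_i]) > HBOND_MIN_ANGLE
        return hit == present
    if entry.contact_class == "salt_bridge":
        grp = [by_name[n] for n in ("OE1", "OE2") if n in by_name]
        dmin = min(np.linalg.norm(coords[g] - coords[l]) for g in grp for l in lig)
        return (dmin <= SALT_BRIDGE_CUTOFF) == present
    if entry.contact_class == "hydrophobic":
        resname = topology.atoms[res_idx[0]].residue_name
        grp = [by_name[n] for n in _PAIR_METRIC_ATOMS["hydrophobic"][resname] if n in by_name]
        dmin = min(np.linalg.norm(coords[g] - coords[l]) for g in grp for l in lig)
        return (dmin <= HYDROPHOBIC_CUTOFF) == present
    if entry.contact_class == "aromatic":
        resname = topology.atoms[res_idx[0]].residue_name
        grp = [by_name[n] for n in _PAIR_METRIC_ATOMS["aromatic"][resname]]
        d = np.linalg.norm(coords[grp].mean(axis=0) - coords[lig].mean(axis=0))
        return (d <= AROMATIC_CENTROID_CUTOFF) == present
    return False


def make_trajectory(topology: MolecularStructure, schedule: ContactSchedule) -> TrajectoryEnsemble:
    """Frame series realising a contact schedule over a complex topology.

    Per frame, each scheduled contact's ligand group is posed inside its
    geometric criteria (with the requested multiplicity) when present and
    well outside them when absent; Gaussian jitter is applied everywhere
    and redrawn for a frame if it would flip a scheduled contact state.
    """
    rng = np.random.default_rng(schedule.seed)
    presence = schedule.presence(rng)
    lig_idx = [i for i, a in enumerate(topology.atoms) if a.residue_name == "LIG"]
    prot_idx = [i for i in range(len(topology)) if i not in set(lig_idx)]
    base = topology.coords
    centroid = base[prot_idx].mean(axis=0)
    poses = [_entry_poses(topology, e, centroid) for e in schedule.entries]
    frames = np.empty((schedule.n_frames, len(topology), 3))
    for k in range(schedule.n_frames):
        for attempt in range(60):
            coords = base.copy()
            for e_i, entry in enumerate(schedule.entries):
                pose = poses[e_i][0] if presence[e_i, k] else poses[e_i][1]
                coords[list(entry.ligand_atoms)] = pose
            coords += rng.normal(scale=schedule.jitter_sigma, size=coords.shape)
            if all(_verify_entry(coords, topology, e, bool(presence[e_i, k]))
                   for e_i, e in enumerate(schedule.entries)):
                frames[k] = coords
                break
        else:
            raise InfeasibleSchedule(f"frame {k}: could not realise the schedule under jitter")
    return TrajectoryEnsemble(topology, frames)


def make_probe_complex(
    entries_spec: list[dict],
    n_frames: int,
    jitter_sigma: float = 0.1,
    seed: int = DEFAULT_SEED,
):
    """Receptor chain + dedicated probe-ligand groups for a contact schedule.

    ``entries_spec`` items: dicts with ``contact_class``, ``residue``
    (chain, resseq), ``p`` and optionally ``mode``, ``multiplicity``,
    ``role``.  Each entry receives its own ligand atom group; when two
    hydrogen-bond entries target the same residue the second group is
    named as a main-chain group so the two occupancy pair rows stay
    distinct.  Returns (trajectory, schedule, ligand InteractionGroups).
    """
    interface, _ = make_toy_interface(seed)
    r_idx = [i for i, a in enumerate(interface.atoms) if a.chain_id == "R"]
    protein = interface.select(r_idx)
    atoms = [AtomRecord(serial=i + 1, name=a.name, element=a.element,
                        residue_name=a.residue_name, residue_seq=a.residue_seq,
                        chain_id=a.chain_id, coords=a.coords.copy(),
                        formal_charge=_RESIDUE_FORMAL_CHARGE.get(a.residue_name, 0)
                        if a.name in ("OE2", "NH1") else 0)
             for i, a in enumerate(protein.atoms)]
    next_idx = len(atoms)
    lig_groups = InteractionGroups()
    entries: list[ScheduleEntry] = []
    hbond_per_residue: dict[tuple, int] = {}
    tag = 0
    for spec in entries_spec:
        cls = spec["contact_class"]
        tag += 1
        if cls == "hbond" and spec.get("role", "ligand_donor") == "ligand_donor":
            seen = hbond_per_residue.get(tuple(spec["residue"]), 0)
            d_name = "N1" if seen == 0 else "N"  # second donor group reads as main-chain
            hbond_per_residue[tuple(spec["residue"])] = seen + 1
            names = [(d_name, "N"), (f"H{tag}", "H")]
            group = (next_idx, next_idx + 1)
            lig_groups.donors.append(group)
        elif cls == "hbond":
            names = [(f"O{tag}", "O")]
            group = (next_idx,)
            lig_groups.acceptors.append(next_idx)
        elif cls == "salt_bridge":
            names = [(f"NQ{tag}", "N")]
            group = (next_idx,)
            lig_groups.charged.append(ChargedGroup(1, group, f"LIG-grp{tag}"))
        elif cls == "hydrophobic":
            names = [(f"C{tag}A", "C"), (f"C{tag}B", "C"), (f"C{tag}C", "C")]
            group = tuple(range(next_idx, next_idx + 3))
            lig_groups.hydrophobic.append((group, f"LIG-grp{tag}"))
        elif cls == "aromatic":
            names = [(f"CR{tag}{chr(65 + i)}", "C") for i in range(6)]
            group = tuple(range(next_idx, next_idx + 6))
            lig_groups.rings.append((group, f"LIG-grp{tag}"))
        else:
            raise InfeasibleSchedule(f"unknown contact class {cls!r}")
        for name, element in names:
            atoms.append(AtomRecord(serial=next_idx + 1, name=name, element=element,
                                    residue_name="LIG", residue_seq=1, chain_id="Z",
                                    coords=np.zeros(3),
                                    formal_charge=1 if cls == "salt_bridge" else 0))
            next_idx += 1
        entries.append(ScheduleEntry(
            contact_class=cls, residue=tuple(spec["residue"]), ligand_atoms=group,
            p=spec["p"], mode=spec.get("mode", "deterministic"),
            multiplicity=spec.get("multiplicity", 1), role=spec.get("role", "ligand_donor"),
        ))
    topology = MolecularStructure(atoms)
    schedule = ContactSchedule(entries=entries, n_frames=n_frames,
                               jitter_sigma=jitter_sigma, seed=seed,
                               metadata={"seed": seed})
    # give ligand groups valid base coordinates (their present poses)
    centroid = topology.coords[[i for i, a in enumerate(atoms) if a.residue_name != "LIG"]].mean(axis=0)
    base = topology.coords
    for entry in entries:
        present, _ = _entry_poses(topology, entry, centroid)
        base[list(entry.ligand_atoms)] = present
    topology = topology.with_coords(base)
    traj = make_trajectory(topology, schedule)
    return traj, schedule, lig_groups


# --------------------------------------------------------------------------
# simple kinematic trajectories for RMSD/RMSF tests
# --------------------------------------------------------------------------

def _chain_topology(coords: np.ndarray, resname="ALA", chain="A") -> MolecularStructure:
    return MolecularStructure([
        AtomRecord(serial=i + 1, name="CA", element="C", residue_name=resname,
                   residue_seq=i + 1, chain_id=chain, coords=c)
        for i, c in enumerate(coords)
    ])


def make_oscillation_trajectory(
    n_atoms: int = 10,
    n_frames: int = 40,
    amplitude: float = 0.5,
    moving_atom: int = 0,
    rigid_motion: bool = False,
    seed: int = DEFAULT_SEED,
) -> TrajectoryEnsemble:
    """Rigid random cloud with one atom alternating +/- amplitude along x.

    The moving atom's fluctuation about the mean structure is exactly the
    amplitude (the others fluctuate only through the superposition), which
    makes the expected RMSF known in closed form.  Optionally every frame
    is additionally subjected to a random global rigid motion.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-5, 5, size=(n_atoms, 3))
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    signs = np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)
    frames[:, moving_atom, 0] += signs * amplitude
    if rigid_motion:
        for k in range(n_frames):
            R = _random_rotation(rng)
            t = rng.uniform(-10, 10, size=3)
            frames[k] = frames[k] @ R.T + t
    return TrajectoryEnsemble(_chain_topology(base), frames)


def make_ligand_shift_trajectory(
    displacement: float = 1.5,
    n_protein: int = 12,
    n_ligand: int = 4,
    n_frames: int = 20,
    seed: int = DEFAULT_SEED,
) -> TrajectoryEnsemble:
    """Rigid protein with the ligand displaced by a fixed offset after frame 0.

    After protein fitting, the ligand RMSD is 0 in frame 0 and exactly the
    displacement magnitude in every later frame.
    """
    rng = np.random.default_rng(seed)
    prot = rng.uniform(-6, 6, size=(n_protein, 3))
    lig = rng.uniform(-2, 2, size=(n_ligand, 3)) + np.array([8.0, 0.0, 0.0])
    atoms = [AtomRecord(serial=i + 1, name="CA", element="C", residue_name="ALA",
                        residue_seq=i + 1, chain_id="A", coords=c) for i, c in enumerate(prot)]
    atoms += [AtomRecord(serial=n_protein + i + 1, name=f"C{i + 1}", element="C",
                         residue_name="LIG", residue_seq=1, chain_id="Z", coords=c)
              for i, c in enumerate(lig)]
    topo = MolecularStructure(atoms)
    shift = np.array([0.0, 0.0, displacement])
    frames = np.repeat(topo.coords[None, :, :], n_frames, axis=0)
    for k in range(1, n_frames):
        frames[k, n_protein:] += shift
        R = _random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
        frames[k] = frames[k] @ R.T + t
    return TrajectoryEnsemble(topo, frames)


# --------------------------------------------------------------------------
# toy force-field parameters
# --------------------------------------------------------------------------

def assign_toy_forcefield(structure: MolecularStructure, seed: int = DEFAULT_SEED,
                          ligand_resname: str = "LIG", **globals_kw) -> ForceFieldParams:
    """Random but physically plausible nonbonded parameters.

    Partial charges are drawn and then shifted so each molecule (protein
    chains together, ligand separately) sums exactly to its formal
    charge; LJ parameters and GB radii land in common force-field ranges
    (GB radii within 1.0-2.5 Å).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = len(structure)
    is_h = np.array([a.element == "H" for a in structure.atoms])
    is_lig = np.array([a.residue_name == ligand_resname for a in structure.atoms])
    charge = rng.normal(scale=0.15, size=n)
    seen_res = set()
    res_charge = np.zeros(n)
    for i, a in enumerate(structure.atoms):
        if a.residue_name != ligand_resname and a.residue_key not in seen_res:
            seen_res.add(a.residue_key)
            res_charge[i] = _RESIDUE_FORMAL_CHARGE.get(a.residue_name, 0)
    lig_formal = sum(a.formal_charge for a in structure.atoms if a.residue_name == ligand_resname)
    for mask, target in ((~is_lig, float(res_charge[~is_lig].sum())), (is_lig, float(lig_formal))):
        if mask.any():
            charge[mask] += (target - charge[mask].sum()) / mask.sum()
    eps = np.where(is_h, rng.uniform(0.015, 0.05, n), rng.uniform(0.05, 0.2, n))
    rmin = np.where(is_h, rng.uniform(0.6, 1.2, n), rng.uniform(1.3, 2.1, n))
    gb = np.where(is_h, rng.uniform(1.0, 1.3, n), rng.uniform(1.4, 2.2, n))
    return ForceFieldParams(charge=charge, lj_epsilon=eps, lj_rmin_half=rmin,
                            gb_radius=gb, **globals_kw)
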
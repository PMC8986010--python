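"""Trajectory stability metrics and geometric interaction analysis.

Implements optimal rigid-body superposition (Kabsch), per-frame RMSD and
per-atom RMSF, geometric detectors for hydrogen bonds, salt bridges,
hydrophobic contacts and aromatic stacking, and contact-occupancy
aggregation: the occupancy of a contact is the mean, over trajectory
frames, of the number of simultaneous instances of that contact, times
100.  Because one residue can hold several simultaneous contacts with a
ligand, per-residue occupancies can legitimately exceed 100%.

Geometric criteria (all configurable):

* hydrogen bond — donor-acceptor distance < 3.5 Å and D-H...A angle > 120 deg,
* salt bridge   — opposite-charge group heavy atoms within 4.0 Å,
* hydrophobic   — carbon-carbon contact within 4.5 Å,
* aromatic      — ring-centroid distance <= 5.5 Å.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MolecularStructure, TrajectoryEnsemble

HBOND_MAX_DA = 3.5
HBOND_MIN_ANGLE = 120.0
SALT_BRIDGE_CUTOFF = 4.0
HYDROPHOBIC_CUTOFF = 4.5
AROMATIC_CENTROID_CUTOFF = 5.5
STRONG_OCCUPANCY_THRESHOLD = 75.0

MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "HA2", "HA3", "H1", "H2", "H3"}


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray, weights=None) -> SuperpositionResult:
    """Optimal proper-rotation + translation of ``mobile`` onto ``reference``.

    Minimises the (weighted) RMSD; reflections are excluded by flipping
    the sign of the smallest singular vector when needed.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference and mobile must both be (N, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mob_c = mob - (w[:, None] * mob).sum(axis=0)
    # degenerate (collinear) configurations have a rank-<2 covariance
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    H = (w[:, None] * mob_c).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = (w[:, None] * ref).sum(axis=0) - R @ (w[:, None] * mob).sum(axis=0)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


@dataclass
class RmsdSeries:
    values: np.ndarray  # per frame, Å
    frame_times: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std())  # population SD over frames

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.frame_times, "rmsd": self.values})


def rmsd_series(
    traj: TrajectoryEnsemble,
    fit_selection,
    measure_selection,
    reference: int = 0,
) -> RmsdSeries:
    """Per-frame RMSD after superposing each frame onto a reference frame.

    The superposition uses ``fit_selection`` only; the RMSD is measured
    over ``measure_selection``.  Passing the protein backbone for both
    gives the protein-stability series; fitting on the protein and
    measuring over ligand heavy atoms gives the ligand-mobility series.
    """
    fit_idx = np.asarray(list(fit_selection), int)
    meas_idx = np.asarray(list(measure_selection), int)
    if fit_idx.size < 3 or meas_idx.size == 0:
        raise ValueError("fit selection needs >= 3 atoms and measure selection must be non-empty")
    if not (0 <= reference < traj.n_frames):
        raise IndexError(f"reference frame {reference} out of range")
    ref_fit = traj.frames[reference][fit_idx]
    ref_meas = traj.frames[reference][meas_idx]
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        sup = kabsch_superpose(ref_fit, traj.frames[k][fit_idx])
        moved = sup.apply(traj.frames[k][meas_idx])
        out[k] = math.sqrt(((moved - ref_meas) ** 2).sum(axis=1).mean())
    return RmsdSeries(out, traj.frame_times.copy())


def rmsf(traj: TrajectoryEnsemble, selection, fit_selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-average structure.

    Two-pass: frames are first superposed onto frame 0, the average
    structure is formed, frames are re-fit onto the average, and
    fluctuations are measured about it.  The superposition uses
    ``fit_selection`` when given (e.g. the rigid core), otherwise the
    measured selection itself.
    """
    idx = np.asarray(list(selection), int)
    fit_idx = idx if fit_selection is None else np.asarray(list(fit_selection), int)
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted_meas = np.empty((traj.n_frames, idx.size, 3))
    fitted_fit = np.empty((traj.n_frames, fit_idx.size, 3))
    ref = traj.frames[0][fit_idx]
    for k in range(traj.n_frames):
        sup = kabsch_superpose(ref, traj.frames[k][fit_idx])
        fitted_meas[k] = sup.apply(traj.frames[k][idx])
        fitted_fit[k] = sup.apply(traj.frames[k][fit_idx])
    avg_fit = fitted_fit.mean(axis=0)
    for k in range(traj.n_frames):
        sup = kabsch_superpose(avg_fit, fitted_fit[k])
        fitted_meas[k] = sup.apply(fitted_meas[k])
    avg = fitted_meas.mean(axis=0)
    return np.sqrt(((fitted_meas - avg) ** 2).sum(axis=2).mean(axis=0))


# --------------------------------------------------------------------------
# interaction groups
# --------------------------------------------------------------------------

@dataclass
class ChargedGroup:
    sign: int
    atoms: tuple[int, ...]
    label: str


@dataclass
class InteractionGroups:
    """Topological annotation of one side (protein or ligand) of a complex.

    Atom indices refer to the complex topology.  ``donors`` are
    (heavy-atom, hydrogen) pairs; the remaining collections are labelled
    atom-index groups.
    """

    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    charged: list[ChargedGroup] = field(default_factory=list)
    hydrophobic: list[tuple[tuple[int, ...], str]] = field(default_factory=list)
    rings: list[tuple[tuple[int, ...], str]] = field(default_factory=list)


_RESIDUE_CHARGED = {"ARG": (1, ("NE", "NH1", "NH2")), "LYS": (1, ("NZ",)),
                    "GLU": (-1, ("OE1", "OE2")), "ASP": (-1, ("OD1", "OD2"))}
_RESIDUE_RINGS = {"PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                  "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                  "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")}
_POLAR_ELEMENTS = {"N", "O", "S"}
_DONOR_H_MAX_DIST = 1.25


def groups_from_structure(structure: MolecularStructure, atom_indices=None) -> InteractionGroups:
    """Derive donors/acceptors/charged/hydrophobic/ring groups for protein residues.

    Donor hydrogens are paired to the nearest N/O/S heavy atom of the same
    residue within 1.25 Å; acceptors are all N/O/S heavy atoms; charged
    groups, rings and side-chain carbon sets come from residue templates.
    """
    if atom_indices is None:
        atom_indices = range(len(structure))
    sel = set(atom_indices)
    groups = InteractionGroups()
    for key in structure.residue_keys:
        res_idx = [i for i in structure.residue_atom_indices(*key) if i in sel]
        if not res_idx:
            continue
        atoms = {structure.atoms[i].name: i for i in res_idx}
        resname = structure.atoms[res_idx[0]].residue_name
        heavy_polar = [i for i in res_idx if structure.atoms[i].element in _POLAR_ELEMENTS]
        groups.acceptors.extend(heavy_polar)
        for i in res_idx:
            if structure.atoms[i].element != "H":
                continue
            best, best_d = None, _DONOR_H_MAX_DIST
            for j in heavy_polar:
                d = float(np.linalg.norm(structure.atoms[i].coords - structure.atoms[j].coords))
                if d < best_d:
                    best, best_d = j, d
            if best is not None:
                groups.donors.append((best, i))
        if resname in _RESIDUE_CHARGED:
            sign, names = _RESIDUE_CHARGED[resname]
            idx = tuple(atoms[n] for n in names if n in atoms)
            if idx:
                groups.charged.append(ChargedGroup(sign, idx, _residue_label(structure, res_idx[0]) + "-Side"))
        sc_carbons = tuple(
            i for i in res_idx
            if structure.atoms[i].element == "C" and structure.atoms[i].name not in MAINCHAIN_ATOMS
            and structure.atoms[i].name != "CB"
        )
        if sc_carbons:
            groups.hydrophobic.append((sc_carbons, _residue_label(structure, res_idx[0]) + "-Side"))
        if resname in _RESIDUE_RINGS:
            names = _RESIDUE_RINGS[resname]
            if all(n in atoms for n in names):
                groups.rings.append((tuple(atoms[n] for n in names), _residue_label(structure, res_idx[0]) + "-Ring"))
    return groups


def _residue_label(structure: MolecularStructure, atom_index: int) -> str:
    a = structure.atoms[atom_index]
    return f"{a.residue_name.capitalize()}{a.residue_seq}"


def _atom_part(structure: MolecularStructure, atom_index: int) -> str:
    return "Main" if structure.atoms[atom_index].name in MAINCHAIN_ATOMS else "Side"


# --------------------------------------------------------------------------
# contact events and detectors
# --------------------------------------------------------------------------

@dataclass
class ContactEvent:
    frame: int
    contact_class: str  # hbond | salt_bridge | hydrophobic | aromatic
    residue: tuple[str, int, str]  # chain, resseq, resname
    protein_atoms: frozenset[int]
    ligand_atoms: frozenset[int]
    role: str  # donor | acceptor | none (role of the protein side)
    distance: float
    angle: float | None = None
    protein_group: str = ""
    ligand_group: str = ""

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.contact_class == "hbond" and not (self.angle is not None and 0 < self.angle <= 180):
            raise ValueError("hbond events need an angle in (0, 180]")


def _residue_of(structure: MolecularStructure, atom_index: int) -> tuple[str, int, str]:
    a = structure.atoms[atom_index]
    return (a.chain_id, a.residue_seq, a.residue_name)


def hbond_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """D-H...A angle at the hydrogen, degrees."""
    v1 = d - h
    v2 = a - h
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def detect_hbonds(
    coords: np.ndarray,
    topology: MolecularStructure,
    protein: InteractionGroups,
    ligand: InteractionGroups,
    frame: int = 0,
    max_da: float = HBOND_MAX_DA,
    min_angle: float = HBOND_MIN_ANGLE,
) -> list[ContactEvent]:
    """One event per satisfying (D, H, A) triple across the protein-ligand divide.

    A triple qualifies when the donor-acceptor distance is strictly below
    ``max_da`` and the D-H...A angle strictly above ``min_angle``.  Each
    qualifying triple is a separate event, so a donor bridging both
    oxygens of a carboxylate contributes two events in that frame.
    """
    events: list[ContactEvent] = []
    for donors, acceptors, protein_is_donor in (
        (protein.donors, ligand.acceptors, True),
        (ligand.donors, protein.acceptors, False),
    ):
        for d_i, h_i in donors:
            for a_i in acceptors:
                r = float(np.linalg.norm(coords[d_i] - coords[a_i]))
                if not (0 < r < max_da):
                    continue
                ang = hbond_angle(coords[d_i], coords[h_i], coords[a_i])
                if ang <= min_angle:
                    continue
                p_atom = d_i if protein_is_donor else a_i
                l_atoms = frozenset({a_i}) if protein_is_donor else frozenset({d_i, h_i})
                p_label = _residue_label(topology, p_atom) + "-" + _atom_part(topology, p_atom)
                l_label = "LIG-" + _atom_part(topology, a_i if protein_is_donor else d_i)
                events.append(ContactEvent(
                    frame=frame, contact_class="hbond", residue=_residue_of(topology, p_atom),
                    protein_atoms=frozenset({p_atom} | ({h_i} if protein_is_donor else set())),
                    ligand_atoms=l_atoms,
                    role="donor" if protein_is_donor else "acceptor",
                    distance=r, angle=ang,
                    protein_group=p_label, ligand_group=l_label,
                ))
    return events


def detect_salt_bridges(
    coords: np.ndarray,
    topology: MolecularStructure,
    protein: InteractionGroups,
    ligand: InteractionGroups,
    frame: int = 0,
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> list[ContactEvent]:
    """One event per opposite-charge group pair with any heavy atoms within the cutoff."""
    events = []
    for pg in protein.charged:
        for lg in ligand.charged:
            if pg.sign * lg.sign >= 0:
                continue
            d = np.linalg.norm(coords[list(pg.atoms)][:, None, :] - coords[list(lg.atoms)][None, :, :], axis=2)
            dmin = float(d.min())
            if dmin <= cutoff:
                events.append(ContactEvent(
                    frame=frame, contact_class="salt_bridge",
                    residue=_residue_of(topology, pg.atoms[0]),
                    protein_atoms=frozenset(pg.atoms), ligand_atoms=frozenset(lg.atoms),
                    role="none", distance=dmin,
                    protein_group=pg.label, ligand_group=lg.label,
                ))
    return events


def detect_hydrophobic(
    coords: np.ndarray,
    topology: MolecularStructure,
    protein: InteractionGroups,
    ligand: InteractionGroups,
    frame: int = 0,
    cutoff: float = HYDROPHOBIC_CUTOFF,
) -> list[ContactEvent]:
    """One event per (residue carbon set, ligand hydrophobic group) within the cutoff."""
    events = []
    for p_atoms, p_label in protein.hydrophobic:
        for l_atoms, l_label in ligand.hydrophobic:
            d = np.linalg.norm(coords[list(p_atoms)][:, None, :] - coords[list(l_atoms)][None, :, :], axis=2)
            dmin = float(d.min())
            if dmin <= cutoff:
                events.append(ContactEvent(
                    frame=frame, contact_class="hydrophobic",
                    residue=_residue_of(topology, p_atoms[0]),
                    protein_atoms=frozenset(p_atoms), ligand_atoms=frozenset(l_atoms),
                    role="none", distance=dmin,
                    protein_group=p_label, ligand_group=l_label,
                ))
    return events


def detect_aromatic(
    coords: np.ndarray,
    topology: MolecularStructure,
    protein: InteractionGroups,
    ligand: InteractionGroups,
    frame: int = 0,
    cutoff: float = AROMATIC_CENTROID_CUTOFF,
) -> list[ContactEvent]:
    """One event per ring pair whose centroids are within the cutoff."""
    events = []
    for p_atoms, p_label in protein.rings:
        pc = coords[list(p_atoms)].mean(axis=0)
        for l_atoms, l_label in ligand.rings:
            lc = coords[list(l_atoms)].mean(axis=0)
            d = float(np.linalg.norm(pc - lc))
            if d <= cutoff:
                events.append(ContactEvent(
                    frame=frame, contact_class="aromatic",
                    residue=_residue_of(topology, p_atoms[0]),
                    protein_atoms=frozenset(p_atoms), ligand_atoms=frozenset(l_atoms),
                    role="none", distance=d,
                    protein_group=p_label, ligand_group=l_label,
                ))
    return events


_DETECTORS = (detect_hbonds, detect_salt_bridges, detect_hydrophobic, detect_aromatic)


def detect_contacts(
    traj: TrajectoryEnsemble,
    protein: InteractionGroups,
    ligand: InteractionGroups,
    classes: tuple[str, ...] = ("hbond", "salt_bridge", "hydrophobic", "aromatic"),
) -> list[ContactEvent]:
    """Run all requested detectors over every frame of a trajectory."""
    by_name = {"hbond": detect_hbonds, "salt_bridge": detect_salt_bridges,
               "hydrophobic": detect_hydrophobic, "aromatic": detect_aromatic}
    events: list[ContactEvent] = []
    for k in range(traj.n_frames):
        for cls in classes:
            events.extend(by_name[cls](traj.frames[k], traj.topology, protein, ligand, frame=k))
    return events


# --------------------------------------------------------------------------
# occupancy aggregation
# --------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Contact occupancies, at pair-level or aggregated per residue.

    ``table`` columns at pair level: chain, resseq, resname, contact_class,
    donor, acceptor, occupancy_percent.  ``residue_level`` sums a residue's
    pair rows, which is why residue occupancies can exceed 100%.
    """

    table: pd.DataFrame
    n_frames: int
    grouping: str = "pair"

    @classmethod
    def from_pair_rows(cls, rows, n_frames: int) -> "OccupancyTable":
        """Build a pair-level table from (residue-label, donor, acceptor, class, occupancy%) rows."""
        recs = []
        for residue, donor, acceptor, contact_class, occ in rows:
            recs.append({
                "chain": "", "resseq": 0, "resname": residue, "residue": residue,
                "contact_class": contact_class, "donor": donor, "acceptor": acceptor,
                "occupancy_percent": float(occ),
            })
        return cls(pd.DataFrame(recs), n_frames=n_frames, grouping="pair")

    def residue_level(self) -> "OccupancyTable":
        """Per-residue aggregate: sum of the residue's pair-level rows (per contact class)."""
        if self.grouping != "pair":
            return self
        agg = (
            self.table.groupby(["residue", "contact_class"], as_index=False)["occupancy_percent"]
            .sum()
        )
        agg["occupancy_percent"] = agg["occupancy_percent"].round(2)
        return OccupancyTable(agg, n_frames=self.n_frames, grouping="residue")

    def occupancy_of(self, residue: str, contact_class: str | None = None) -> float:
        t = self.table[self.table["residue"] == residue]
        if contact_class is not None:
            t = t[t["contact_class"] == contact_class]
        return float(t["occupancy_percent"].sum())


def occupancy(events: list[ContactEvent], n_frames: int, grouping: str = "pair") -> OccupancyTable:
    """Aggregate contact events into an occupancy table.

    A pair row is a specific (residue group, ligand group, contact class,
    role) combination; its occupancy is 100/N times the number of events
    of that pair across all frames (multiplicity counted).  Residue-level
    rows are the sums of a residue's pair rows.
    """
    if n_frames <= 0:
        raise ValueError("occupancy needs a trajectory with at least one frame")
    recs = []
    for ev in events:
        chain, resseq, resname = ev.residue
        if ev.contact_class == "hbond":
            donor, acceptor = (ev.protein_group, ev.ligand_group) if ev.role == "donor" else (ev.ligand_group, ev.protein_group)
        else:
            donor, acceptor = ev.protein_group, ev.ligand_group
        recs.append({
            "chain": chain, "resseq": resseq, "resname": resname,
            "residue": f"{resname.capitalize()}{resseq}",
            "contact_class": ev.contact_class, "donor": donor, "acceptor": acceptor,
        })
    if not recs:
        table = pd.DataFrame(columns=["chain", "resseq", "resname", "residue",
                                      "contact_class", "donor", "acceptor", "occupancy_percent"])
        out = OccupancyTable(table, n_frames=n_frames, grouping="pair")
        return out.residue_level() if grouping == "residue" else out
    df = pd.DataFrame(recs)
    counts = (
        df.groupby(["chain", "resseq", "resname", "residue", "contact_class", "donor", "acceptor"])
        .size().reset_index(name="n_events")
    )
    counts["occupancy_percent"] = (100.0 * counts["n_events"] / n_frames).round(2)
    counts = counts.drop(columns="n_events")
    out = OccupancyTable(counts, n_frames=n_frames, grouping="pair")
    return out.residue_level() if grouping == "residue" else out


def strong_hbond_flag(table: OccupancyTable, threshold: float = STRONG_OCCUPANCY_THRESHOLD) -> pd.DataFrame:
    """Rows whose occupancy strictly exceeds the threshold (default 75%)."""
    t = table.table.copy()
    t["strong"] = t["occupancy_percent"] > threshold
    return t[t["strong"]]
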
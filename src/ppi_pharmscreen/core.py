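"""Domain containers and plain-text IO.

Holds the three in-memory objects the rest of the package operates on —
protein structures (:class:`MolecularStructure`), small molecules with 3D
conformers (:class:`SmallMolecule`) and frame series
(:class:`TrajectoryEnsemble`) — together with readers/writers for PDB,
SDF (V2000, via RDKit) and XYZ frame series.  All internal lengths are in
Å, times in ns and energies in kcal/mol; docking scores arrive in kJ/mol
and are converted explicitly.
"""
from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

KJ_PER_KCAL = 4.184


def kj_to_kcal(x: float) -> float:
    """Convert kJ/mol to kcal/mol (factor 4.184)."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL


class ParseError(ValueError):
    """Raised when a text format cannot be parsed; message names the location."""


# --------------------------------------------------------------------------
# atoms and structures
# --------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom of a structure.

    ``partial_charge``/``lj_*``/``gb_radius`` are optional force-field
    annotations used by the MM-GBSA stage; plain structural work leaves
    them ``None``.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    formal_charge: int = 0
    partial_charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    gb_radius: float | None = None
    insertion_code: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: element symbol is empty")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


class MolecularStructure:
    """Ordered atom list plus a (chain, residue) index."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        if len(atoms) == 0:
            raise ValueError("structure must contain at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)
        self._residues: dict[tuple[str, int, str], list[int]] = {}
        seen: set[tuple[str, int, str, str]] = set()
        for i, a in enumerate(self.atoms):
            ident = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
            if ident in seen:
                raise ValueError(f"duplicate atom identity {ident}")
            seen.add(ident)
            self._residues.setdefault(a.residue_key, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        return list(self._residues)

    def residue_atom_indices(self, chain_id: str, residue_seq: int, insertion_code: str = "") -> list[int]:
        key = (chain_id, residue_seq, insertion_code)
        if key not in self._residues:
            raise KeyError(f"no residue {key} in structure")
        return list(self._residues[key])

    def residue_name(self, chain_id: str, residue_seq: int, insertion_code: str = "") -> str:
        return self.atoms[self.residue_atom_indices(chain_id, residue_seq, insertion_code)[0]].residue_name

    def atom_index(self, chain_id: str, residue_seq: int, name: str, insertion_code: str = "") -> int:
        for i in self.residue_atom_indices(chain_id, residue_seq, insertion_code):
            if self.atoms[i].name == name:
                return i
        raise KeyError(f"no atom {name} in residue {(chain_id, residue_seq)}")

    def select(self, indices: Iterable[int]) -> "MolecularStructure":
        return MolecularStructure([replace(self.atoms[i], coords=self.atoms[i].coords.copy()) for i in indices])

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate array shape mismatch")
        return MolecularStructure([replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)])


# --------------------------------------------------------------------------
# small molecules
# --------------------------------------------------------------------------

@dataclass
class SmallMolecule:
    """Bonded small-molecule topology with one or more 3D conformers.

    ``bonds`` are (i, j, order) with order 1/2/3 or 1.5 for aromatic;
    ``properties`` carries SDF data fields such as a precomputed logP.
    """

    elements: list[str]
    formal_charges: list[int]
    bonds: list[tuple[int, int, float]]
    conformers: list[np.ndarray]
    properties: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        if len(self.formal_charges) != n:
            raise ValueError("formal_charges length mismatch")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) has invalid endpoints")
        self.conformers = [np.asarray(c, float) for c in self.conformers]
        for k, c in enumerate(self.conformers):
            if c.shape != (n, 3):
                raise ValueError(f"conformer {k} has shape {c.shape}, expected ({n}, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, o in self.bonds:
            if a == i:
                out.append((b, o))
            elif b == i:
                out.append((a, o))
        return out


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

DEFAULT_FRAME_STRIDE_NS = 0.01  # save interval of the production runs being emulated


class TrajectoryEnsemble:
    """Frame series over a fixed complex topology; ligand atoms flagged by residue name."""

    def __init__(
        self,
        topology: MolecularStructure,
        frames: np.ndarray,
        frame_times: np.ndarray | None = None,
        ligand_resname: str = "LIG",
    ):
        frames = np.asarray(frames, float)
        if frames.ndim != 3 or frames.shape[1] != len(topology) or frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (F, {len(topology)}, 3), got {frames.shape}")
        if frame_times is None:
            frame_times = DEFAULT_FRAME_STRIDE_NS * np.arange(1, frames.shape[0] + 1)
        frame_times = np.asarray(frame_times, float)
        if frame_times.shape != (frames.shape[0],):
            raise ValueError("frame_times length mismatch")
        if frames.shape[0] > 1 and not np.all(np.diff(frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.frame_times = frame_times
        self.ligand_resname = ligand_resname
        self.ligand_indices = np.array(
            [i for i, a in enumerate(topology.atoms) if a.residue_name == ligand_resname], dtype=int
        )
        self.protein_indices = np.array(
            [i for i, a in enumerate(topology.atoms) if a.residue_name != ligand_resname], dtype=int
        )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# --------------------------------------------------------------------------
# IO helpers
# --------------------------------------------------------------------------

def _open_text(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_text(source) -> str:
    if isinstance(source, str) and "\n" in source:
        return source
    fh = _open_text(source)
    try:
        return fh.read()
    finally:
        if fh is not source:
            fh.close()


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip() or " "
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed residue number: {line[22:26]!r}") from exc
    icode = line[26:27].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed coordinate field") from exc
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip()
    if not element:
        # fall back to the first alphabetic character of the atom name
        stripped = name.lstrip("0123456789")
        element = (stripped[:2].strip() if stripped[:2] in ("CL", "BR") else stripped[:1]) or "X"
    return AtomRecord(
        serial=serial, name=name, element=element.capitalize(),
        residue_name=resname, residue_seq=resseq, chain_id=chain,
        coords=np.array([x, y, z]), insertion_code=icode, occupancy=occupancy,
    )


def read_pdb(source) -> MolecularStructure:
    """Read ATOM/HETATM records of (the first model of) a PDB stream.

    Alternate locations are resolved to the highest occupancy, ties to the
    first encountered.  Raises :class:`ParseError` naming the offending
    line on malformed coordinates, and on empty input.
    """
    text = _read_text(source)
    best: dict[tuple, tuple[float, int, AtomRecord]] = {}
    order: list[tuple] = []
    n_seen = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[0:6]
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM  ", "HETATM"):
            continue
        atom = _parse_pdb_atom(line, lineno)
        n_seen += 1
        ident = (atom.chain_id, atom.residue_seq, atom.insertion_code, atom.name)
        if ident not in best:
            best[ident] = (atom.occupancy, n_seen, atom)
            order.append(ident)
        elif atom.occupancy > best[ident][0]:
            best[ident] = (atom.occupancy, best[ident][1], atom)
    if not best:
        raise ParseError("no ATOM/HETATM records found in input")
    return MolecularStructure([best[i][2] for i in order])


def _format_pdb_atom(a: AtomRecord, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain_id:1.1s}"
        f"{a.residue_seq:4d}{a.insertion_code:<1.1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element.upper():>2.2s}"
    )


def write_pdb(structure: MolecularStructure, target) -> None:
    lines = [_format_pdb_atom(a, i + 1) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "wt") as fh:
            fh.write(text)


# --------------------------------------------------------------------------
# SDF (via RDKit)
# --------------------------------------------------------------------------

_BOND_ORDER_FROM_RDKIT = {1.0: 1.0, 2.0: 2.0, 3.0: 3.0, 1.5: 1.5}


def read_sdf(source) -> list[SmallMolecule]:
    """Read a (multi-record) V2000/V3000 SD file into :class:`SmallMolecule` objects.

    Data fields are copied into ``properties``; a field named logP (any
    capitalisation) is additionally exposed as ``properties['logP']``.
    """
    from rdkit import Chem

    text = _read_text(source)
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=False, removeHs=False)
    out: list[SmallMolecule] = []
    for ri, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"SDF record {ri + 1}: unreadable connection table")
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        elements = [at.GetSymbol() for at in mol.GetAtoms()]
        charges = [at.GetFormalCharge() for at in mol.GetAtoms()]
        bonds = []
        for b in mol.GetBonds():
            order = b.GetBondTypeAsDouble()
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER_FROM_RDKIT.get(order, order)))
        coords = (
            np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
                      for i in range(mol.GetNumAtoms())])
            if conf is not None else np.zeros((mol.GetNumAtoms(), 3))
        )
        props = dict(mol.GetPropsAsDict())
        for key in list(props):
            if key.lower() == "logp":
                props["logP"] = float(props[key])
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append(SmallMolecule(elements, charges, bonds, [coords], props, name))
    return out


def write_sdf(mols: Sequence[SmallMolecule], target, conformer: int = 0) -> None:
    """Write molecules as a V2000 SD file (one record per molecule)."""
    buf = io.StringIO()
    for mol in mols:
        coords = mol.conformers[conformer]
        buf.write(f"{mol.name}\n  ppiphs3D\n\n")
        buf.write(f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000\n")
        for i, el in enumerate(mol.elements):
            x, y, z = coords[i]
            buf.write(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3.3s} 0  0  0  0  0  0  0  0  0  0  0  0\n")
        for i, j, o in mol.bonds:
            order = 4 if o == 1.5 else int(o)
            buf.write(f"{i + 1:3d}{j + 1:3d}{order:3d}  0\n")
        charged = [(i, q) for i, q in enumerate(mol.formal_charges) if q]
        if charged:
            buf.write(f"M  CHG{len(charged):3d}" + "".join(f"{i + 1:4d}{q:4d}" for i, q in charged) + "\n")
        buf.write("M  END\n")
        for key, val in mol.properties.items():
            buf.write(f"> <{key}>\n{val}\n\n")
        buf.write("$$$$\n")
    text = buf.getvalue()
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "wt") as fh:
            fh.write(text)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def read_trajectory(
    topology: MolecularStructure,
    source,
    dialect: str = "multi-model-pdb",
    stride_ns: float = DEFAULT_FRAME_STRIDE_NS,
    ligand_resname: str = "LIG",
) -> TrajectoryEnsemble:
    """Read a frame series (multi-model PDB or XYZ) over a known topology.

    Frame times are assigned from the configured stride (default 0.01 ns
    per frame).  A frame whose atom count differs from the topology raises
    an error naming the frame index.
    """
    text = _read_text(source)
    n = len(topology)
    frames: list[np.ndarray] = []
    if dialect in ("multi-model-pdb", "pdb"):
        current: list[list[float]] = []
        in_any_model = "MODEL" in text
        for lineno, line in enumerate(text.splitlines(), start=1):
            rec = line[0:6]
            if rec in ("ATOM  ", "HETATM"):
                atom = _parse_pdb_atom(line, lineno)
                current.append(list(atom.coords))
            elif rec == "ENDMDL" or (rec.startswith("END") and not in_any_model):
                if current:
                    frames.append(np.array(current))
                    current = []
        if current:
            frames.append(np.array(current))
    elif dialect in ("xyz-frames", "xyz"):
        lines = text.splitlines()
        pos = 0
        while pos < len(lines):
            if not lines[pos].strip():
                pos += 1
                continue
            try:
                count = int(lines[pos].strip())
            except ValueError as exc:
                raise ParseError(f"line {pos + 1}: expected atom count") from exc
            block = lines[pos + 2: pos + 2 + count]
            if len(block) < count:
                raise ParseError(f"frame {len(frames)}: truncated XYZ block")
            frame = []
            for rel, ln in enumerate(block):
                parts = ln.split()
                try:
                    frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"line {pos + 3 + rel}: malformed XYZ atom line") from exc
            frames.append(np.array(frame))
            pos += 2 + count
    else:
        raise ValueError(f"unknown trajectory dialect: {dialect!r}")
    if not frames:
        raise ParseError("no frames found in trajectory input")
    for k, f in enumerate(frames):
        if f.shape[0] != n:
            raise ParseError(f"frame {k}: has {f.shape[0]} atoms, topology has {n}")
    arr = np.stack(frames)
    times = stride_ns * np.arange(1, arr.shape[0] + 1)
    return TrajectoryEnsemble(topology, arr, times, ligand_resname=ligand_resname)


def write_trajectory(traj: TrajectoryEnsemble, target, dialect: str = "multi-model-pdb") -> None:
    buf = io.StringIO()
    if dialect in ("multi-model-pdb", "pdb"):
        for k in range(traj.n_frames):
            buf.write(f"MODEL {k + 1:8d}\n")
            frame_struct = traj.topology.with_coords(traj.frames[k])
            for i, a in enumerate(frame_struct.atoms):
                buf.write(_format_pdb_atom(a, i + 1) + "\n")
            buf.write("ENDMDL\n")
        buf.write("END\n")
    elif dialect in ("xyz-frames", "xyz"):
        for k in range(traj.n_frames):
            buf.write(f"{len(traj.topology)}\nframe {k} t={traj.frame_times[k]:.4f} ns\n")
            for i, a in enumerate(traj.topology.atoms):
                x, y, z = traj.frames[k, i]
                buf.write(f"{a.element:<2.2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")
    else:
        raise ValueError(f"unknown trajectory dialect: {dialect!r}")
    text = buf.getvalue()
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "wt") as fh:
            fh.write(text)
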
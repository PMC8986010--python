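"""Single-trajectory MM-GBSA binding free-energy decomposition.

The binding free energy of each frame is the end-state difference

    dG_bind = G(complex) - G(protein) - G(ligand)

with all three geometries taken from the complex frame (single-trajectory
approximation), so intramolecular bonded terms cancel exactly and the
gas-phase part reduces to the protein-ligand cross van der Waals and
Coulomb sums.  The polar solvation term is a generalized-Born model with
OBC-rescaled effective radii (parameter set I: alpha 0.8, beta 0, gamma
2.909125); the nonpolar term is gamma_SASA * SASA + beta_SASA over a
Shrake-Rupley surface with a deterministic spiral point set.  The
conformational-entropy term is deliberately omitted: for ranking ligands
against one protein its contribution to the differences is small.

Units: kcal/mol, Å, elementary charges; the Coulomb constant is
332.0636 kcal*Å/(mol*e^2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MolecularStructure, TrajectoryEnsemble

COULOMB = 332.0636
OBC1_ALPHA, OBC1_BETA, OBC1_GAMMA = 0.8, 0.0, 2.909125


@dataclass
class ForceFieldParams:
    """Per-atom nonbonded parameters plus global solvation settings."""

    charge: np.ndarray          # e
    lj_epsilon: np.ndarray      # kcal/mol
    lj_rmin_half: np.ndarray    # Å
    gb_radius: np.ndarray       # Å (intrinsic Born radii)
    eps_in: float = 1.0
    eps_out: float = 78.5
    sasa_gamma: float = 0.0072  # kcal/mol/Å^2
    sasa_beta: float = 0.0      # kcal/mol
    probe_radius: float = 1.4   # Å
    gb_offset: float = 0.0      # Å subtracted from intrinsic radii before descreening
    gb_screen: np.ndarray | None = None  # HCT screening factors (default 0.8)
    sasa_n_points: int = 960

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, float)
        self.gb_radius = np.asarray(self.gb_radius, float)
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("dielectric constants must be positive")
        if np.any(self.gb_radius <= 0):
            raise ValueError("GB radii must be positive")
        if self.gb_screen is None:
            self.gb_screen = np.full(self.charge.shape, 0.8)
        else:
            self.gb_screen = np.asarray(self.gb_screen, float)

    @property
    def n_atoms(self) -> int:
        return int(self.charge.shape[0])

    def subset(self, indices) -> "ForceFieldParams":
        idx = np.asarray(list(indices), int)
        return ForceFieldParams(
            charge=self.charge[idx], lj_epsilon=self.lj_epsilon[idx],
            lj_rmin_half=self.lj_rmin_half[idx], gb_radius=self.gb_radius[idx],
            eps_in=self.eps_in, eps_out=self.eps_out,
            sasa_gamma=self.sasa_gamma, sasa_beta=self.sasa_beta,
            probe_radius=self.probe_radius, gb_offset=self.gb_offset,
            gb_screen=self.gb_screen[idx], sasa_n_points=self.sasa_n_points,
        )

    @classmethod
    def from_structure(cls, structure: MolecularStructure, **kw) -> "ForceFieldParams":
        missing = [a.name for a in structure.atoms
                   if a.partial_charge is None or a.lj_epsilon is None
                   or a.lj_rmin_half is None or a.gb_radius is None]
        if missing:
            raise ValueError(f"atoms lacking force-field parameters: {missing}")
        return cls(
            charge=np.array([a.partial_charge for a in structure.atoms]),
            lj_epsilon=np.array([a.lj_epsilon for a in structure.atoms]),
            lj_rmin_half=np.array([a.lj_rmin_half for a in structure.atoms]),
            gb_radius=np.array([a.gb_radius for a in structure.atoms]),
            **kw,
        )


# --------------------------------------------------------------------------
# molecular-mechanics cross terms
# --------------------------------------------------------------------------

def pairwise_mm(coords: np.ndarray, params: ForceFieldParams, pairs) -> tuple[float, float]:
    """(E_vdW, E_elec) in kcal/mol summed over explicit atom pairs, no cutoff.

    Coulomb: 332.0636 q_i q_j / (eps_in r).  Lennard-Jones 12-6 in the
    Rmin/epsilon convention with epsilon_ij the geometric and Rmin_ij the
    arithmetic combination.
    """
    coords = np.asarray(coords, float)
    e_vdw = 0.0
    e_elec = 0.0
    for i, j in pairs:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        if r == 0.0:
            raise ValueError(f"zero interatomic distance in pair ({i}, {j})")
        eps = math.sqrt(params.lj_epsilon[i] * params.lj_epsilon[j])
        rmin = params.lj_rmin_half[i] + params.lj_rmin_half[j]
        q = (rmin / r) ** 6
        e_vdw += eps * (q * q - 2.0 * q)
        e_elec += COULOMB * params.charge[i] * params.charge[j] / (params.eps_in * r)
    return e_vdw, e_elec


def cross_mm(coords: np.ndarray, params: ForceFieldParams, group_a, group_b) -> tuple[float, float]:
    """Vectorised protein-ligand cross sums of the pairwise MM terms."""
    ia = np.asarray(list(group_a), int)
    ib = np.asarray(list(group_b), int)
    d = np.linalg.norm(coords[ia][:, None, :] - coords[ib][None, :, :], axis=2)
    if np.any(d == 0):
        raise ValueError("zero interatomic distance between the two groups")
    eps = np.sqrt(np.outer(params.lj_epsilon[ia], params.lj_epsilon[ib]))
    rmin = params.lj_rmin_half[ia][:, None] + params.lj_rmin_half[ib][None, :]
    q6 = (rmin / d) ** 6
    e_vdw = float((eps * (q6 * q6 - 2.0 * q6)).sum())
    e_elec = float((COULOMB * np.outer(params.charge[ia], params.charge[ib]) / (params.eps_in * d)).sum())
    return e_vdw, e_elec


# --------------------------------------------------------------------------
# generalized Born (OBC)
# --------------------------------------------------------------------------

def effective_born_radii(coords: np.ndarray, params: ForceFieldParams) -> np.ndarray:
    """OBC effective Born radii from the pairwise descreening integral.

    The Hawkins-Cramer-Truhlar integral I_i is accumulated over all
    neighbours, Psi_i = I_i * rho_i, and the effective radius follows the
    OBC rescaling 1/R_i = 1/rho_i - tanh(alpha Psi - beta Psi^2 +
    gamma Psi^3)/rho0_i with parameter set I.
    """
    coords = np.asarray(coords, float)
    n = params.n_atoms
    rho0 = params.gb_radius            # intrinsic radii
    rho = rho0 - params.gb_offset      # descreening radii
    if np.any(rho <= 0):
        bad = int(np.argmax(rho <= 0))
        raise ValueError(f"nonpositive descreening radius for atom {bad}")
    integral = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            s = params.gb_screen[j] * rho[j]
            if rho[i] >= r + s:
                continue  # neighbour fully inside atom i
            upper = r + s
            lower = max(abs(r - s), rho[i])
            term = (
                1.0 / lower - 1.0 / upper
                + 0.25 * (r - s * s / r) * (1.0 / (upper * upper) - 1.0 / (lower * lower))
                + 0.5 / r * math.log(lower / upper)
            )
            integral[i] += 0.5 * term
    psi = integral * rho
    scale = np.tanh(OBC1_ALPHA * psi - OBC1_BETA * psi ** 2 + OBC1_GAMMA * psi ** 3)
    inv_r = 1.0 / rho - scale / rho0
    if np.any(inv_r <= 0):
        bad = int(np.argmax(inv_r <= 0))
        raise ValueError(f"nonpositive effective Born radius for atom {bad}")
    return 1.0 / inv_r


def gb_polar(coords: np.ndarray, params: ForceFieldParams, radii: np.ndarray | None = None) -> float:
    """Generalized-Born polar solvation energy, kcal/mol.

    dG = -1/2 (1/eps_in - 1/eps_out) * 332.0636 * sum_ij q_i q_j / f_ij
    with f_ij = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j)); the i = j terms
    are the Born self energies (f_ii = R_i).
    """
    coords = np.asarray(coords, float)
    if radii is None:
        radii = effective_born_radii(coords, params)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff ** 2).sum(axis=2)
    rr = np.outer(radii, radii)
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    tau = 1.0 / params.eps_in - 1.0 / params.eps_out
    qq = np.outer(params.charge, params.charge)
    return float(-0.5 * tau * COULOMB * (qq / f).sum())


# --------------------------------------------------------------------------
# solvent-accessible surface area
# --------------------------------------------------------------------------

def _spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (Fibonacci) unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(n)
    cos_theta = 1.0 - 2.0 * k / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta ** 2, 0.0, 1.0))
    return np.column_stack([np.cos(phi) * sin_theta, np.sin(phi) * sin_theta, cos_theta])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area, per atom and total (Å^2)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("SASA radii must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    unit = _spiral_points(n_points)
    ext = radii + probe_radius
    n = coords.shape[0]
    per_atom = np.zeros(n)
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            # neighbour prefilter: spheres must overlap to occlude
            dij = np.linalg.norm(coords[i] - coords[j])
            if dij >= ext[i] + ext[j]:
                continue
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
            if not accessible.any():
                break
        per_atom[i] = 4.0 * math.pi * ext[i] ** 2 * accessible.mean()
    return per_atom, float(per_atom.sum())


# --------------------------------------------------------------------------
# per-frame decomposition
# --------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    """All Delta terms of the decomposition, per frame, with mean +/- SD.

    Bookkeeping identities (held per frame by construction):
    dG_gas = dE_bond + dE_vdW + dE_elec, dG_solv = dG_GB + dG_SA,
    dG_bind = dG_gas + dG_solv.  dE_bond is identically zero in the
    single-trajectory approximation; the entropy term is omitted.
    """

    frames: pd.DataFrame = field(repr=False)

    TERMS = ("dE_vdW", "dE_elec", "dG_GB", "dG_SA", "dG_gas", "dG_solv", "dG_bind")

    def mean(self, term: str) -> float:
        return float(self.frames[term].mean())

    def sd(self, term: str) -> float:
        return float(self.frames[term].std(ddof=0))  # population SD over frames

    def summary(self) -> pd.DataFrame:
        rows = [{"term": t, "mean_kcal_mol": self.mean(t), "sd_kcal_mol": self.sd(t)}
                for t in self.TERMS]
        return pd.DataFrame(rows)

    @property
    def dE_bond(self) -> float:
        return 0.0


def binding_energy(
    traj: TrajectoryEnsemble,
    params: ForceFieldParams,
    stride: int = 1,
) -> EnergyDecomposition:
    """MM-GBSA decomposition over (strided) frames of a complex trajectory.

    Complex, protein and ligand geometries are all extracted from the
    complex frame, so the gas-phase Delta terms are exactly the
    protein-ligand cross-interaction sums and dE_bond vanishes.
    """
    if params.n_atoms != len(traj.topology):
        raise ValueError("parameter table does not match topology atom count")
    if traj.ligand_indices.size == 0 or traj.protein_indices.size == 0:
        raise ValueError("trajectory must contain both protein and flagged ligand atoms")
    p_idx = traj.protein_indices
    l_idx = traj.ligand_indices
    p_par = params.subset(p_idx)
    l_par = params.subset(l_idx)
    rows = []
    for k in range(0, traj.n_frames, stride):
        xyz = traj.frames[k]
        de_vdw, de_elec = cross_mm(xyz, params, p_idx, l_idx)
        gb_c = gb_polar(xyz, params)
        gb_p = gb_polar(xyz[p_idx], p_par)
        gb_l = gb_polar(xyz[l_idx], l_par)
        dg_gb = gb_c - gb_p - gb_l
        _, sasa_c = sasa(xyz, params.gb_radius, params.probe_radius, params.sasa_n_points)
        _, sasa_p = sasa(xyz[p_idx], p_par.gb_radius, params.probe_radius, params.sasa_n_points)
        _, sasa_l = sasa(xyz[l_idx], l_par.gb_radius, params.probe_radius, params.sasa_n_points)
        dg_sa = params.sasa_gamma * (sasa_c - sasa_p - sasa_l) - params.sasa_beta
        dg_gas = 0.0 + de_vdw + de_elec
        dg_solv = dg_gb + dg_sa
        rows.append({
            "frame": k, "time_ns": traj.frame_times[k],
            "dE_vdW": de_vdw, "dE_elec": de_elec, "dG_GB": dg_gb, "dG_SA": dg_sa,
            "dG_gas": dg_gas, "dG_solv": dg_solv, "dG_bind": dg_gas + dg_solv,
        })
    return EnergyDecomposition(frames=pd.DataFrame(rows))
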
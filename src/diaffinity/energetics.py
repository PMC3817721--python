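"""Per-residue protein-ligand interaction energetics.

The van der Waals channel uses a softened Lennard-Jones 8-4 potential,

    E(r) = eps * [ (R_e / r)**8 - 2 * (R_e / r)**4 ],

whose minimum is -eps at the equilibrium distance R_e.  Relative to the
conventional 12-6 form, the shallower r^-4 attraction folds a short-range
hydrophobic attraction into the same term.  The electrostatic channel is a
plain Coulomb sum; a per-ligand-atom effective dielectric constant
(ratio of vacuum to solvated force magnitudes, softened by an exponent)
optionally scales it.

All pairwise sums run protein-atom x ligand-atom with AMBER-style
combination rules: R_e(a,b) = rmin(a) + rmin(b) (each atom contributing its
half of the homodimer minimum) and eps(a,b) = sqrt(eps(a) * eps(b)).
Water and ion atoms never enter the residue-ligand sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "WATER_DIELECTRIC",
    "ResidueEnergyProfile",
    "DielectricMap",
    "lj84_pair",
    "coulomb_pair",
    "residue_ligand_energies",
    "trajectory_profile",
    "effective_dielectric",
    "dielectric_scale",
    "estimate_forces",
    "dielectric_map_from_trajectory",
    "modified_electrostatics",
]

#: Coulomb constant in kcal Å / (mol e^2).
COULOMB_CONSTANT = 332.0636
#: Bulk dielectric constant of water; upper clamp for the effective dielectric.
WATER_DIELECTRIC = 78.5

_OVERLAP_TOL = 1e-6


@dataclass
class ResidueEnergyProfile:
    """Trajectory-averaged residue-ligand energies and their fluctuations.

    Arrays are ordered like ``Topology.protein_residues``.  ``mean_ele_mod``
    equals ``mean_ele`` until a dielectric map is applied.
    """

    residue_ids: np.ndarray
    mean_vdw: np.ndarray
    mean_ele: np.ndarray
    fluct_vdw: np.ndarray
    fluct_ele: np.ndarray
    mean_ele_mod: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fluct_vdw < 0) or np.any(self.fluct_ele < 0):
            raise ValueError("fluctuations must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "mean_vdw": self.mean_vdw,
                "mean_ele": self.mean_ele,
                "fluct_vdw": self.fluct_vdw,
                "fluct_ele": self.fluct_ele,
                "mean_ele_mod": self.mean_ele_mod,
            }
        )


@dataclass
class DielectricMap:
    """Per-ligand-atom effective dielectric constants and scale factors."""

    ligand_atom_indices: np.ndarray
    eps_eff: np.ndarray
    exponent: float = 0.6

    def __post_init__(self) -> None:
        self.eps_eff = np.asarray(self.eps_eff, dtype=float)
        if np.any(self.eps_eff < 1.0):
            raise ValueError("eps_eff must be >= 1 after clamping")
        if not 0.0 <= self.exponent <= 1.0:
            raise ValueError("dielectric exponent must lie in [0, 1]")

    @property
    def scales(self) -> np.ndarray:
        return dielectric_scale(self.eps_eff, self.exponent)


# ---------------------------------------------------------------------------
# Pair potentials
# ---------------------------------------------------------------------------

def lj84_pair(r, r_e, eps):
    """Lennard-Jones 8-4 energy (kcal/mol) of one atom pair.

    Minimum of -eps at r = r_e; crosses zero at 2**(-1/4) * r_e.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lj84_pair: r must be positive")
    q = (np.asarray(r_e, dtype=float) / r) ** 4
    return np.asarray(eps, dtype=float) * (q * q - 2.0 * q)


def coulomb_pair(r, qi, qj):
    """Coulomb energy (kcal/mol) of a point-charge pair at distance r (Å)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("coulomb_pair: r must be positive")
    return COULOMB_CONSTANT * np.asarray(qi) * np.asarray(qj) / r


# ---------------------------------------------------------------------------
# Per-frame residue-ligand decomposition
# ---------------------------------------------------------------------------

def _pair_tables(topology: Topology):
    """Pre-computed combination-rule tables for protein x ligand pairs."""
    prot = topology.protein_atom_indices
    lig = topology.ligand_atom_indices
    rmin = topology.lj_rmin()
    eps = topology.lj_eps()
    q = topology.charges()
    r_e = rmin[prot][:, None] + rmin[lig][None, :]
    eps_ab = np.sqrt(eps[prot][:, None] * eps[lig][None, :])
    qq = q[prot][:, None] * q[lig][None, :]
    return prot, lig, r_e, eps_ab, qq


def _pair_distances(frame: np.ndarray, prot: np.ndarray, lig: np.ndarray) -> np.ndarray:
    d = frame[prot][:, None, :] - frame[lig][None, :, :]
    r = np.linalg.norm(d, axis=2)
    if np.any(r < _OVERLAP_TOL):
        a, b = np.argwhere(r < _OVERLAP_TOL)[0]
        raise ValueError(f"overlapping atoms: protein atom {prot[a]} / ligand atom {lig[b]}")
    return r


def residue_ligand_energies(
    frame: np.ndarray, topology: Topology, cutoff: float | None = None
):
    """Single-frame (E_vdw(i), E_ele(i)) for every protein residue i.

    Each residue energy is the sum over all its atoms paired with all ligand
    atoms; no distance cutoff is applied by default.
    """
    frame = np.asarray(frame, dtype=float)
    prot, lig, r_e, eps_ab, qq = _pair_tables(topology)
    if prot.size == 0 or lig.size == 0:
        raise ValueError("topology needs at least one protein residue and a ligand")
    r = _pair_distances(frame, prot, lig)
    q4 = (r_e / r) ** 4
    e_vdw_pairs = eps_ab * (q4 * q4 - 2.0 * q4)
    e_ele_pairs = COULOMB_CONSTANT * qq / r
    if cutoff is not None:
        mask = r < cutoff
        e_vdw_pairs = np.where(mask, e_vdw_pairs, 0.0)
        e_ele_pairs = np.where(mask, e_ele_pairs, 0.0)
    pres = topology.protein_residues
    pos = {idx: k for k, idx in enumerate(prot)}
    e_vdw = np.zeros(len(pres))
    e_ele = np.zeros(len(pres))
    for i, res in enumerate(pres):
        rows = [pos[a] for a in res.atom_indices]
        e_vdw[i] = e_vdw_pairs[rows].sum()
        e_ele[i] = e_ele_pairs[rows].sum()
    return e_vdw, e_ele


def trajectory_profile(
    traj: Trajectory, topology: Topology, cutoff: float | None = None
) -> ResidueEnergyProfile:
    """Trajectory mean and population-SD fluctuation of the residue energies."""
    per_frame_vdw = []
    per_frame_ele = []
    for m in range(traj.n_frames):
        ev, ee = residue_ligand_energies(traj.frames[m], topology, cutoff=cutoff)
        per_frame_vdw.append(ev)
        per_frame_ele.append(ee)
    vdw = np.array(per_frame_vdw)
    ele = np.array(per_frame_ele)
    mean_ele = ele.mean(axis=0)
    return ResidueEnergyProfile(
        residue_ids=np.array([r.residue_id for r in topology.protein_residues]),
        mean_vdw=vdw.mean(axis=0),
        mean_ele=mean_ele,
        fluct_vdw=vdw.std(axis=0),
        fluct_ele=ele.std(axis=0),
        mean_ele_mod=mean_ele.copy(),
    )


# ---------------------------------------------------------------------------
# Effective dielectric
# ---------------------------------------------------------------------------

def effective_dielectric(f_real: np.ndarray, f_vac: np.ndarray) -> float:
    """eps_eff = |F_vac| / |F_real|, clamped into [1, 78.5].

    A vanishing solvated force (the solvent almost exactly cancels the field)
    would blow the ratio up, so it clamps to the bulk water value; a vanishing
    vacuum force carries no information and defaults to 1.
    """
    nv = float(np.linalg.norm(f_vac))
    nr = float(np.linalg.norm(f_real))
    if nv < _OVERLAP_TOL:
        return 1.0
    if nr < _OVERLAP_TOL:
        return WATER_DIELECTRIC
    return float(np.clip(nv / nr, 1.0, WATER_DIELECTRIC))


def dielectric_scale(eps_eff, exponent: float = 0.6):
    """Softened inverse-power scale s = eps_eff**(-exponent), in (0, 1]."""
    eps_eff = np.asarray(eps_eff, dtype=float)
    if np.any(eps_eff < 1.0):
        raise ValueError("eps_eff must be >= 1")
    if not 0.0 <= exponent <= 1.0:
        raise ValueError("exponent must lie in [0, 1]")
    return eps_eff ** (-exponent)


def _coulomb_forces_on(
    frame: np.ndarray, targets: np.ndarray, sources: np.ndarray, charges: np.ndarray
) -> np.ndarray:
    """Coulomb force vectors (kcal/mol/Å) on each target from all sources."""
    forces = np.zeros((targets.size, 3))
    for k, j in enumerate(targets):
        src = sources[sources != j]
        if src.size == 0:
            continue
        d = frame[j] - frame[src]  # points source -> target
        r = np.linalg.norm(d, axis=1)
        if np.any(r < _OVERLAP_TOL):
            raise ValueError(f"overlapping atoms around ligand atom {j}")
        f = COULOMB_CONSTANT * charges[j] * charges[src] / r**3
        forces[k] = (f[:, None] * d).sum(axis=0)
    return forces


def estimate_forces(topology: Topology, frame: np.ndarray):
    """Static per-ligand-atom Coulomb forces (f_vac, f_real) for one frame.

    f_vac sums protein+ligand sources only; f_real additionally includes
    water and ion sources.  With no waters present a warning is emitted and
    f_real equals f_vac (eps_eff -> 1).
    """
    frame = np.asarray(frame, dtype=float)
    q = topology.charges()
    lig = topology.ligand_atom_indices
    solute = np.concatenate([topology.protein_atom_indices, lig])
    solvent = np.concatenate([topology.water_atom_indices, topology.ion_atom_indices])
    f_vac = _coulomb_forces_on(frame, lig, solute, q)
    if solvent.size == 0:
        warnings.warn("no water/ion atoms: f_real equals f_vac (eps_eff -> 1)", stacklevel=2)
        return f_vac, f_vac.copy()
    f_real = f_vac + _coulomb_forces_on(frame, lig, solvent, q)
    return f_vac, f_real


def dielectric_map_from_trajectory(
    traj: Trajectory, topology: Topology, exponent: float = 0.6
) -> DielectricMap:
    """Effective dielectric per ligand atom from frame-averaged force magnitudes."""
    lig = topology.ligand_atom_indices
    nv = np.zeros(lig.size)
    nr = np.zeros(lig.size)
    for m in range(traj.n_frames):
        f_vac, f_real = estimate_forces(topology, traj.frames[m])
        nv += np.linalg.norm(f_vac, axis=1)
        nr += np.linalg.norm(f_real, axis=1)
    nv /= traj.n_frames
    nr /= traj.n_frames
    eps = np.array(
        [effective_dielectric(np.array([r, 0, 0]), np.array([v, 0, 0])) for v, r in zip(nv, nr)]
    )
    return DielectricMap(ligand_atom_indices=lig, eps_eff=eps, exponent=exponent)


def modified_electrostatics(
    traj: Trajectory, topology: Topology, dielectric: DielectricMap
) -> np.ndarray:
    """Trajectory-averaged dielectric-scaled electrostatics per residue.

    E_mod(i) = < sum_j s_j * E_j(i) >  with E_j(i) the vacuum Coulomb
    interaction between residue i and ligand atom j.  All scales equal to 1
    reduce this to the unmodified mean electrostatic profile.
    """
    lig = topology.ligand_atom_indices
    if dielectric.ligand_atom_indices.shape != lig.shape or np.any(
        dielectric.ligand_atom_indices != lig
    ):
        raise ValueError("dielectric map must cover exactly the ligand atoms")
    s = dielectric.scales
    prot, lig_idx, _, _, qq = _pair_tables(topology)
    pres = topology.protein_residues
    pos = {idx: k for k, idx in enumerate(prot)}
    acc = np.zeros(len(pres))
    for m in range(traj.n_frames):
        r = _pair_distances(traj.frames[m], prot, lig_idx)
        scaled = (COULOMB_CONSTANT * qq / r) * s[None, :]
        for i, res in enumerate(pres):
            rows = [pos[a] for a in res.atom_indices]
            acc[i] += scaled[rows].sum()
    return acc / traj.n_frames


def apply_dielectric(
    profile: ResidueEnergyProfile,
    traj: Trajectory,
    topology: Topology,
    dielectric: DielectricMap,
) -> ResidueEnergyProfile:
    """Return a copy of *profile* with ``mean_ele_mod`` filled in."""
    mod = modified_electrostatics(traj, topology, dielectric)
    return ResidueEnergyProfile(
        residue_ids=profile.residue_ids.copy(),
        mean_vdw=profile.mean_vdw.copy(),
        mean_ele=profile.mean_ele.copy(),
        fluct_vdw=profile.fluct_vdw.copy(),
        fluct_ele=profile.fluct_ele.copy(),
        mean_ele_mod=mod,
    )
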
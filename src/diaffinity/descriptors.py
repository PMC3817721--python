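"""Conformational-entropy proxy descriptors.

Two system-level fluctuation measures enter the binding models through the
tau-weighted entropy term: S_DIH, the summed circular standard deviation of
the protein dihedral angles over the trajectory, and S_ASA, the standard
deviation of the per-frame accessible surface area of the protein-ligand
complex.  A per-ligand descriptor, the non-ring rotatable-bond count N_rot,
carries the conformational entropy the ligand loses on binding: each
rotatable bond multiplies the free-ligand conformer count by roughly 3, and
the fitted coefficient w (kcal/mol per bond) absorbs the kT*ln3 prefactor
together with intramolecular-clash corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import Topology, Trajectory

__all__ = [
    "GlobalDescriptors",
    "dihedral_angles",
    "dihedral_fluctuation",
    "asa_total",
    "asa_fluctuation",
    "count_rotatable",
    "ligand_entropy_term",
    "ring_entropy_conformers",
]


@dataclass
class GlobalDescriptors:
    s_dih: float  # degrees
    s_asa: float  # Å^2
    n_rot: int
    n_rot_ring: int

    def __post_init__(self) -> None:
        if self.s_dih < 0 or self.s_asa < 0:
            raise ValueError("fluctuation descriptors must be non-negative")
        if self.n_rot < 0 or self.n_rot_ring < 0:
            raise ValueError("rotatable-bond counts must be non-negative")


# ---------------------------------------------------------------------------
# Dihedral fluctuation
# ---------------------------------------------------------------------------

def dihedral_angles(traj: Trajectory, quads) -> np.ndarray:
    """Dihedral angles in degrees, shape (n_frames, n_quads)."""
    from MDAnalysis.lib.distances import calc_dihedrals

    quads = [tuple(q) for q in quads]
    if not quads:
        return np.zeros((traj.n_frames, 0))
    ai, bi, ci, di = (np.array([q[k] for q in quads]) for k in range(4))
    out = np.empty((traj.n_frames, len(quads)))
    for m in range(traj.n_frames):
        f = traj.frames[m]
        # a collinear bonded triple leaves the torsion undefined
        n1 = np.cross(f[bi] - f[ai], f[ci] - f[bi])
        n2 = np.cross(f[ci] - f[bi], f[di] - f[ci])
        degenerate = (np.linalg.norm(n1, axis=1) < 1e-8) | (np.linalg.norm(n2, axis=1) < 1e-8)
        ang = calc_dihedrals(f[ai], f[bi], f[ci], f[di])
        if np.any(degenerate | ~np.isfinite(ang)):
            bad = quads[int(np.flatnonzero(degenerate | ~np.isfinite(ang))[0])]
            raise ValueError(f"undefined dihedral (collinear atoms) for quad {bad} in frame {m}")
        out[m] = np.degrees(ang)
    return out


def _circular_population_sd(angles_deg: np.ndarray) -> np.ndarray:
    """Wrap-aware population SD (degrees) per dihedral, column-wise.

    Deviations from the circular mean are wrapped into (-180, 180] before the
    ordinary population SD, so an alternation between 179 and -179 degrees
    has a fluctuation of 1 degree, not 179.
    """
    rad = np.radians(angles_deg)
    mean = np.arctan2(np.sin(rad).mean(axis=0), np.cos(rad).mean(axis=0))
    dev = np.degrees((rad - mean + np.pi) % (2 * np.pi) - np.pi)
    return dev.std(axis=0)


def dihedral_fluctuation(traj: Trajectory, quads) -> float:
    """S_DIH: sum over dihedrals of the circular population SD (degrees)."""
    angles = dihedral_angles(traj, quads)
    if angles.shape[1] == 0 or traj.n_frames == 1:
        return 0.0
    return float(_circular_population_sd(angles).sum())


# ---------------------------------------------------------------------------
# Accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere points (golden-spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def asa_total(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Shrake-Rupley accessible surface area (Å^2) of a set of spheres.

    Each atom's extended sphere (radius + probe) is sampled with a fixed
    golden-spiral point set; a point counts as accessible when it lies
    outside every other atom's extended sphere.  Deterministic for a given
    ``n_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or probe < 0:
        raise ValueError("radii must be positive and probe non-negative")
    unit = _sphere_points(n_points)
    ext = radii + probe
    area = 0.0
    for i in range(coords.shape[0]):
        pts = coords[i] + ext[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(coords.shape[0]):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) >= ext[i] + ext[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= ext[j] ** 2
        area += 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return float(area)


def _complex_heavy_selection(topology: Topology):
    idx = [
        a.index
        for a in topology.atoms
        if a.role in ("protein", "ligand") and a.is_heavy
    ]
    radii = np.array([topology.atoms[i].radius for i in idx])
    return np.array(idx, dtype=int), radii


def asa_fluctuation(
    traj: Trajectory,
    topology: Topology,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """S_ASA: population SD (Å^2) of the complex heavy-atom ASA over frames."""
    idx, radii = _complex_heavy_selection(topology)
    areas = np.array(
        [asa_total(traj.frames[m][idx], radii, probe, n_points) for m in range(traj.n_frames)]
    )
    return float(areas.std())


# ---------------------------------------------------------------------------
# Rotatable bonds and the ligand entropy term
# ---------------------------------------------------------------------------

def count_rotatable(
    topology: Topology, include_terminal: bool = False
) -> tuple[int, int]:
    """(n_rot, n_rot_ring) for the ligand bond graph.

    n_rot counts non-ring single bonds between heavy atoms; by default bonds
    to a terminal heavy atom are excluded because rotating them generates no
    new heavy-atom conformer.  n_rot_ring counts ring-member heavy-atom
    single bonds.  Bond orders must be annotated for every ligand bond.
    """
    lig_atoms = set(topology.ligand_atom_indices.tolist())
    heavy = {i for i in lig_atoms if topology.atoms[i].is_heavy}
    lig_bonds = [
        (i, j) for (i, j) in topology.bonds if i in lig_atoms and j in lig_atoms
    ]
    for b in lig_bonds:
        if b not in topology.bond_orders:
            raise ValueError(f"missing bond-order annotation for ligand bond {b}")
    g = nx.Graph((i, j) for (i, j) in lig_bonds if i in heavy and j in heavy)
    ring_edges: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add(frozenset((a, b)))
    n_rot = 0
    n_rot_ring = 0
    for i, j in lig_bonds:
        if i not in heavy or j not in heavy:
            continue
        if topology.bond_orders[(i, j)] != 1:
            continue
        if frozenset((i, j)) in ring_edges:
            n_rot_ring += 1
            continue
        if not include_terminal:
            if g.degree(i) < 2 or g.degree(j) < 2:
                continue
        n_rot += 1
    return n_rot, n_rot_ring


def ligand_entropy_term(n_rot: int, w: float) -> float:
    """T*dS penalty (kcal/mol) for freezing n_rot rotatable bonds: w * n_rot.

    The per-bond coefficient w is a fitted parameter; any kT*ln3 factor from
    the ~3**n_rot conformer count is absorbed into it.
    """
    if n_rot < 0:
        raise ValueError("n_rot must be non-negative")
    return w * n_rot


def ring_entropy_conformers(n_rot_ring: int, base: int = 2) -> float:
    """Approximate ring-part conformer count, base**(n_rot_ring - 3).

    Rings with three or fewer rotatable bonds have a single conformer.
    Computed for diagnostics only; no fitted model includes it, as adding it
    does not improve the regression.
    """
    if base not in (2, 3):
        raise ValueError("base must be 2 or 3")
    return float(base ** max(0, n_rot_ring - 3))
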
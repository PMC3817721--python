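"""Residue-level water mobility analysis.

Pocket residues that hold their hydration water tightly mark interaction
hot spots: displacing a strongly bound water on ligand binding is favorable.
Two per-residue mobility measures are computed from an apo-protein
trajectory:

* ``h_w`` — the water exchange rate: for each atom j of residue i, the 6 Å
  hydration shell (water membership by oxygen position) is tracked from one
  sampled frame to the next, and the number of waters exchanged per atom per
  sampled transition is averaged over the residue,

      h_w(i) = sum_m sum_{j in i} dn_j^m / (N_i * (Nstep - 1)),

  where dn_j^m is half the symmetric difference of the shells at steps m-1
  and m (a one-for-one swap counts as one exchange) and N_i counts all atoms
  of the residue, hydrogens included.

* ``h_c`` — the mean contact number: protein atoms (solvent and ligand
  excluded) within 6 Å of atom j, averaged per atom per frame.  Buried
  pocket-bottom atoms have large contact numbers and immobile waters, so
  h_c serves as a solvent-free proxy for (low) water mobility.

Residue weights exp(gamma * H_i) then scale each residue's interaction
energies in the weighted binding models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Residue, Topology, Trajectory

__all__ = [
    "HydrationProfile",
    "hydration_shell",
    "exchange_rate",
    "contact_number",
    "contact_rate",
    "residue_weights",
    "hydration_profile",
]

DEFAULT_CUTOFF = 6.0  # Å


@dataclass
class HydrationProfile:
    """Per-protein-residue water mobility and exp(gamma*H) weights."""

    residue_ids: np.ndarray
    h_w: np.ndarray  # exchanged waters / atom / sampled transition
    h_c: np.ndarray  # contact atoms / atom / frame
    c_avg: float  # global mean contact number (reported, not a normalizer)

    def __post_init__(self) -> None:
        if np.any(self.h_w < 0) or np.any(self.h_c < 0):
            raise ValueError("hydration measures must be non-negative")

    def weights(self, gamma: float, source: str = "water_exchange") -> np.ndarray:
        h = self.h_w if source == "water_exchange" else self.h_c
        return residue_weights(h, gamma)

    def to_frame(self, gamma: float = 0.0):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "h_w": self.h_w,
                "h_c": self.h_c,
                "weight": residue_weights(self.h_w, gamma),
            }
        )


def _water_oxygen_indices(topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """(oxygen atom index, water residue id) per water, membership by oxygen."""
    ox, rid = [], []
    for res in topology.water_residues:
        oxy = [i for i in res.atom_indices if topology.atoms[i].element.upper() == "O"]
        # fall back to the first atom for coarse water models lacking elements
        ox.append(oxy[0] if oxy else res.atom_indices[0])
        rid.append(res.residue_id)
    return np.array(ox, dtype=int), np.array(rid, dtype=int)


def hydration_shell(
    frame: np.ndarray,
    topology: Topology,
    atom_j: int,
    cutoff: float = DEFAULT_CUTOFF,
) -> set[int]:
    """Water residue ids whose oxygen lies strictly within *cutoff* of atom_j."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ox, rid = _water_oxygen_indices(topology)
    if ox.size == 0:
        return set()
    d = np.linalg.norm(np.asarray(frame)[ox] - np.asarray(frame)[atom_j], axis=1)
    return set(rid[d < cutoff].tolist())


def exchange_rate(
    traj: Trajectory,
    topology: Topology,
    residue: Residue | int,
    cutoff: float = DEFAULT_CUTOFF,
    counting: str = "symmetric",
) -> float:
    """Residue water-exchange rate h_w (waters / atom / sampled transition).

    ``counting='symmetric'`` scores half the symmetric shell difference per
    transition (a one-for-one swap is one event, time-reversal symmetric);
    ``'departures'`` counts leaving waters only.
    """
    if traj.n_frames < 2:
        raise ValueError("exchange rate undefined for a single-frame trajectory")
    if counting not in ("symmetric", "departures"):
        raise ValueError("counting must be 'symmetric' or 'departures'")
    res = topology.residues[residue] if isinstance(residue, int) else residue
    n_i = len(res.atom_indices)
    total = 0.0
    prev = [
        hydration_shell(traj.frames[0], topology, j, cutoff) for j in res.atom_indices
    ]
    for m in range(1, traj.n_frames):
        for k, j in enumerate(res.atom_indices):
            cur = hydration_shell(traj.frames[m], topology, j, cutoff)
            if counting == "symmetric":
                total += len(prev[k] ^ cur) / 2.0
            else:
                total += len(prev[k] - cur)
            prev[k] = cur
    return total / (n_i * (traj.n_frames - 1))


def contact_number(
    frame: np.ndarray,
    topology: Topology,
    atom_j: int,
    cutoff: float = DEFAULT_CUTOFF,
) -> int:
    """Protein atoms (self excluded; solvent/ligand never counted) within cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot = topology.protein_atom_indices
    prot = prot[prot != atom_j]
    if prot.size == 0:
        return 0
    d = np.linalg.norm(np.asarray(frame)[prot] - np.asarray(frame)[atom_j], axis=1)
    return int(np.count_nonzero(d < cutoff))


def contact_rate(
    traj: Trajectory,
    topology: Topology,
    residue: Residue | int,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Mean contact number h_c of a residue (atoms / atom / frame)."""
    res = topology.residues[residue] if isinstance(residue, int) else residue
    n_i = len(res.atom_indices)
    total = 0
    for m in range(traj.n_frames):
        for j in res.atom_indices:
            total += contact_number(traj.frames[m], topology, j, cutoff)
    return total / (n_i * traj.n_frames)


def residue_weights(h_values: np.ndarray, gamma: float) -> np.ndarray:
    """Residue weights exp(gamma * H_i); gamma = 0 gives unit weights."""
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    return np.exp(gamma * np.asarray(h_values, dtype=float))


def hydration_profile(
    traj: Trajectory,
    topology: Topology,
    cutoff: float = DEFAULT_CUTOFF,
    counting: str = "symmetric",
) -> HydrationProfile:
    """h_w and h_c for every protein residue, plus the global mean contact."""
    pres = topology.protein_residues
    h_w = np.array(
        [exchange_rate(traj, topology, r, cutoff, counting) for r in pres]
        if traj.n_frames >= 2
        else [0.0] * len(pres)
    )
    h_c = np.array([contact_rate(traj, topology, r, cutoff) for r in pres])
    # global per-atom per-frame mean contact number
    n_atoms = sum(len(r.atom_indices) for r in pres)
    c_avg = float(sum(h * len(r.atom_indices) for h, r in zip(h_c, pres)) / n_atoms) if n_atoms else 0.0
    return HydrationProfile(
        residue_ids=np.array([r.residue_id for r in pres]),
        h_w=h_w,
        h_c=h_c,
        c_avg=c_avg,
    )
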
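import numpy as np
import pytest

from diaffinity.io import Atom, Residue, Topology, Trajectory
from diaffinity.synth import SyntheticSpec, make_toy_complex, simulate_harmonic_trajectory


def build_topology(atom_rows, residue_rows, bonds=None):
    """Compact topology builder for hand-crafted test systems.

    atom_rows: (element, charge, lj_rmin, lj_eps, residue_id, role) per atom.
    residue_rows: (label, role, atom_index_tuple) per residue.
    """
    atoms = [
        Atom(index=i, element=el, charge=q, lj_rmin=rm, lj_eps=ep, residue_id=rid, role=role,
             name=f"{el}{i}", serial=i + 1)
        for i, (el, q, rm, ep, rid, role) in enumerate(atom_rows)
    ]
    residues = [Residue(k, lab, role, tuple(idx)) for k, (lab, role, idx) in enumerate(residue_rows)]
    bonds = bonds or {}
    return Topology(atoms=atoms, residues=residues, bonds=sorted(bonds), bond_orders=dict(bonds))


@pytest.fixture
def pair_system():
    """One single-atom protein residue + one single-atom ligand."""
    def make(q_prot=0.0, q_lig=0.0, rmin=1.5, eps=0.2):
        return build_topology(
            [("C", q_prot, rmin, eps, 0, "protein"), ("C", q_lig, rmin, eps, 1, "ligand")],
            [("GLY", "protein", (0,)), ("LIG", "ligand", (1,))],
        )
    return make


@pytest.fixture(scope="session")
def toy():
    spec = SyntheticSpec(seed=11, n_residues=3, atoms_per_residue=4, ligand_atom_count=4,
                         n_waters=20, n_frames=50, fluctuation_amplitude=0.2,
                         shell_swap_prob=0.05)
    topo, ref = make_toy_complex(spec)
    traj = simulate_harmonic_trajectory(topo, ref, spec)
    return spec, topo, ref, traj


def static_trajectory(frame, n_frames=5, dt=2.0):
    return Trajectory(np.repeat(np.asarray(frame, dtype=float)[None], n_frames, axis=0), dt)
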
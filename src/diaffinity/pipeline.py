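"""End-to-end characterization of one complex from topology + ensemble."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .descriptors import asa_fluctuation, count_rotatable, dihedral_fluctuation
from .energetics import apply_dielectric, dielectric_map_from_trajectory, trajectory_profile
from .hydration import hydration_profile
from .io import Topology, Trajectory
from .models import ComplexData

__all__ = ["characterize_complex"]


def characterize_complex(
    topology: Topology,
    traj: Trajectory,
    complex_id: str = "complex",
    dg_exptl: float = 0.0,
    apo_traj: Optional[Trajectory] = None,
    apo_topology: Optional[Topology] = None,
    dielectric_exponent: Optional[float] = None,
    compute_asa: bool = False,
    cutoff: Optional[float] = None,
) -> ComplexData:
    """Run the full descriptor pipeline on one complex.

    The hydration profile is measured on the apo-protein trajectory when one
    is supplied (the intended protocol), otherwise on the complex trajectory
    itself.  Dielectric-scaled electrostatics are computed only when
    *dielectric_exponent* is given (needed for the solvent-scaled model);
    the ASA fluctuation only on request, as the dihedral channel is the
    default entropy proxy.
    """
    profile = trajectory_profile(traj, topology, cutoff=cutoff)
    if dielectric_exponent is not None:
        dmap = dielectric_map_from_trajectory(traj, topology, exponent=dielectric_exponent)
        profile = apply_dielectric(profile, traj, topology, dmap)
    h_topo = apo_topology if apo_topology is not None else topology
    h_traj = apo_traj if apo_traj is not None else traj
    hyd = hydration_profile(h_traj, h_topo)
    if len(hyd.residue_ids) != len(profile.residue_ids):
        raise ValueError("apo topology must share the complex's protein residues")
    s_dih = dihedral_fluctuation(traj, topology.dihedral_quads)
    s_asa = asa_fluctuation(traj, topology) if compute_asa else 0.0
    n_rot, _ = count_rotatable(topology)
    return ComplexData(
        complex_id=complex_id,
        dg_exptl=dg_exptl,
        e_vdw=profile.mean_vdw,
        e_ele=profile.mean_ele,
        s_vdw=profile.fluct_vdw,
        s_ele=profile.fluct_ele,
        h_w=hyd.h_w,
        h_c=hyd.h_c,
        s_dih=float(s_dih),
        s_asa=float(s_asa),
        n_rot=int(n_rot),
        e_ele_mod=np.asarray(profile.mean_ele_mod),
    )
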
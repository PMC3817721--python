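"""Readers and writers for annotated topologies, conformational ensembles and
binding free-energy tables.

A *topology* couples a PDB file (coordinates, residue grouping, CONECT
records) with a sidecar parameter table that supplies, per (residue name,
atom name): the partial charge (e), the per-atom Lennard-Jones minimum-energy
radius contribution R_min/2 (Å), the well depth epsilon (kcal/mol) and an
optional hard-sphere radius used for surface-area calculations.  No force
field typing is performed here: parameters are taken verbatim from the table.

Conventions: coordinates in Å, energies in kcal/mol, charges in units of the
elementary charge, time in ps.  Atom indices are 0-based internally; the PDB
serial of every atom is preserved for reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "DGRecord",
    "TopologyError",
    "TrajectoryError",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "read_dg_table",
    "write_dg_table",
]

#: Residue names mapped onto the protein role.
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}
WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "T3P"}
ION_NAMES = {"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "MG2", "CA", "CA2", "ZN", "BR", "F", "IOD"}


class TopologyError(ValueError):
    """Raised when a topology cannot be assembled consistently."""


class TrajectoryError(ValueError):
    """Raised when a coordinate ensemble is malformed."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    charge: float
    lj_rmin: float
    lj_eps: float
    residue_id: int
    role: str
    name: str = ""
    serial: int = 0
    radius: float = 1.7  # hard-sphere radius for ASA, Å

    def __post_init__(self) -> None:
        if self.lj_eps < 0:
            raise TopologyError(f"atom {self.name or self.index}: lj_eps must be >= 0")
        if self.lj_rmin <= 0:
            raise TopologyError(f"atom {self.name or self.index}: lj_rmin must be > 0")
        if self.role not in ("protein", "ligand", "water", "ion"):
            raise TopologyError(f"atom {self.name or self.index}: unknown role {self.role!r}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Residue:
    residue_id: int
    label: str
    role: str
    atom_indices: tuple[int, ...]


@dataclass
class Topology:
    """Atoms grouped into residues, with bonds, rings and dihedral quads."""

    atoms: list[Atom]
    residues: list[Residue]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    bond_orders: dict[tuple[int, int], int] = field(default_factory=dict)
    dihedral_quads: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[int] = set()
        for res in self.residues:
            for i in res.atom_indices:
                if not 0 <= i < n:
                    raise TopologyError(f"residue {res.residue_id} references atom {i} out of range")
                if i in seen:
                    raise TopologyError(f"atom {i} belongs to more than one residue")
                seen.add(i)
        if len(seen) != n:
            raise TopologyError("every atom must belong to exactly one residue")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i}, {j}) references an invalid atom")
        for res in self.residues:
            if res.role == "water" and len(res.atom_indices) != 3:
                raise TopologyError(
                    f"water residue {res.residue_id} has {len(res.atom_indices)} atoms; expected 3"
                )
        if sum(1 for r in self.residues if r.role == "ligand") != 1:
            raise TopologyError("topology must contain exactly one ligand residue")

    # -- role-based selections (cached lazily) --------------------------------
    def _role_idx(self, role: str) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.role == role], dtype=int)

    @property
    def protein_atom_indices(self) -> np.ndarray:
        return self._role_idx("protein")

    @property
    def ligand_atom_indices(self) -> np.ndarray:
        return self._role_idx("ligand")

    @property
    def water_atom_indices(self) -> np.ndarray:
        return self._role_idx("water")

    @property
    def ion_atom_indices(self) -> np.ndarray:
        return self._role_idx("ion")

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.role == "protein"]

    @property
    def ligand_residue(self) -> Residue:
        return next(r for r in self.residues if r.role == "ligand")

    @property
    def water_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.role == "water"]

    def ring_bonds(self) -> set[frozenset[int]]:
        """Bonds that are part of at least one cycle of the bond graph."""
        g = nx.Graph(self.bonds)
        rings: set[frozenset[int]] = set()
        for cycle in nx.cycle_basis(g):
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                rings.add(frozenset((a, b)))
        return rings

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def lj_rmin(self) -> np.ndarray:
        return np.array([a.lj_rmin for a in self.atoms])

    def lj_eps(self) -> np.ndarray:
        return np.array([a.lj_eps for a in self.atoms])


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) at a fixed sampling interval (ps)."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt_sample: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError("frames must have shape (n_frames, n_atoms, 3)")
        if self.dt_sample <= 0:
            raise TrajectoryError("dt_sample must be > 0")
        if self.n_frames < 1:
            raise TrajectoryError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class DGRecord:
    """One protein-ligand complex in a binding free-energy dataset."""

    complex_id: str
    dg_exptl: float
    features: dict = field(default_factory=dict)
    docking_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.dg_exptl):
            raise ValueError(f"{self.complex_id}: dg_exptl must be finite")


# ---------------------------------------------------------------------------
# Topology reading
# ---------------------------------------------------------------------------

def _infer_role(resname: str, ligand_resname: Optional[str]) -> Optional[str]:
    name = resname.strip().upper()
    if ligand_resname is not None and name == ligand_resname.strip().upper():
        return "ligand"
    if name in STANDARD_AMINO_ACIDS:
        return "protein"
    if name in WATER_NAMES:
        return "water"
    if name in ION_NAMES:
        return "ion"
    return None  # het residue: ligand candidate


def _parse_pdb_atoms(pdb_path: Path) -> list[dict]:
    """File-ordered atom records of the first model, via Bio.PDB."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    out = []
    for chain in model:
        for res in chain:
            for atom in res:
                x, y, z = atom.coord
                element = (atom.element or atom.get_name()[:1]).strip()
                out.append(
                    dict(
                        serial=atom.serial_number,
                        name=atom.get_name(),
                        resname=res.get_resname().strip(),
                        chain=chain.id,
                        resseq=res.id[1],
                        x=float(x),
                        y=float(y),
                        z=float(z),
                        element=element.capitalize(),
                    )
                )
    return out


def _parse_conect(lines: Iterable[str]) -> dict[tuple[int, int], int]:
    """CONECT records as (serial_i, serial_j) -> multiplicity (bond order)."""
    counts: dict[tuple[int, int], int] = {}
    for line in lines:
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11]] + [line[11 + 5 * k : 16 + 5 * k] for k in range(4)]
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 2:
            continue
        a = int(fields[0])
        for b in map(int, fields[1:]):
            key = (min(a, b), max(a, b))
            counts[key] = counts.get(key, 0) + 1
    # CONECT is reciprocal: each bond appears from both atoms
    return {k: max(1, v // 2) for k, v in counts.items()}


def read_topology(
    pdb_path: str | Path,
    param_table: str | Path,
    ligand_resname: Optional[str] = None,
    bond_table: Optional[str | Path] = None,
) -> Topology:
    """Build a :class:`Topology` from a PDB file plus a parameter sidecar.

    Parameters
    ----------
    pdb_path:
        PDB file; the first MODEL provides the reference coordinates used for
        distance-based bond completion of standard residues.
    param_table:
        CSV with columns ``residue_name, atom_name, element, charge, lj_rmin,
        lj_eps`` and optionally ``radius``.
    ligand_resname:
        Residue name to treat as the ligand.  Required when more than one
        non-standard (het) residue is present.
    bond_table:
        Optional CSV ``serial_i, serial_j, order`` overriding/augmenting the
        CONECT records (used to carry bond orders for the ligand graph).
    """
    pdb_path = Path(pdb_path)
    lines = pdb_path.read_text().splitlines()
    raw_atoms = _parse_pdb_atoms(pdb_path)
    if not raw_atoms:
        raise TopologyError(f"{pdb_path}: no ATOM/HETATM records found")
    serials = [a["serial"] for a in raw_atoms]
    if len(set(serials)) != len(serials):
        raise TopologyError(f"{pdb_path}: duplicate atom serials")

    params = pd.read_csv(param_table)
    params.columns = [c.strip() for c in params.columns]
    key_cols = {"residue_name", "atom_name"}
    if not key_cols.issubset(params.columns):
        raise TopologyError(f"{param_table}: parameter table needs columns {sorted(key_cols)}")
    lookup = {
        (str(r.residue_name).strip().upper(), str(r.atom_name).strip().upper()): r
        for r in params.itertuples()
    }

    # group file-ordered atoms into residues by (chain, resseq, resname)
    res_keys: list[tuple] = []
    res_members: dict[tuple, list[int]] = {}
    for i, a in enumerate(raw_atoms):
        key = (a["chain"], a["resseq"], a["resname"])
        if key not in res_members:
            res_keys.append(key)
            res_members[key] = []
        res_members[key].append(i)

    roles: dict[tuple, str] = {}
    het_keys = []
    for key in res_keys:
        role = _infer_role(key[2], ligand_resname)
        if role is None:
            het_keys.append(key)
        else:
            roles[key] = role
    if het_keys:
        names = sorted({k[2] for k in het_keys})
        if ligand_resname is not None:
            raise TopologyError(
                f"unresolved het residues besides designated ligand: {', '.join(names)}"
            )
        if len(het_keys) > 1:
            raise TopologyError(
                f"{len(het_keys)} het residues ({', '.join(names)}) but no ligand_resname designated"
            )
        roles[het_keys[0]] = "ligand"
    if not any(r == "ligand" for r in roles.values()):
        raise TopologyError(
            f"no ligand residue found"
            + (f" (designated {ligand_resname!r})" if ligand_resname else "")
        )

    atoms: list[Atom] = []
    residues: list[Residue] = []
    for rid, key in enumerate(res_keys):
        members = res_members[key]
        for i in members:
            a = raw_atoms[i]
            pkey = (a["resname"].upper(), a["name"].upper())
            if pkey not in lookup:
                raise TopologyError(
                    f"no parameters for atom {a['name']} in residue {a['resname']} "
                    f"(serial {a['serial']})"
                )
            row = lookup[pkey]
            atoms.append(
                Atom(
                    index=i,
                    element=str(getattr(row, "element", a["element"])).strip(),
                    charge=float(row.charge),
                    lj_rmin=float(row.lj_rmin),
                    lj_eps=float(row.lj_eps),
                    residue_id=rid,
                    role=roles[key],
                    name=a["name"],
                    serial=a["serial"],
                    radius=float(getattr(row, "radius", 1.7)),
                )
            )
        residues.append(Residue(rid, key[2], roles[key], tuple(members)))
    atoms.sort(key=lambda a: a.index)

    serial_to_index = {a.serial: a.index for a in atoms}
    bond_orders: dict[tuple[int, int], int] = {}
    for (sa, sb), order in _parse_conect(lines).items():
        if sa in serial_to_index and sb in serial_to_index:
            i, j = sorted((serial_to_index[sa], serial_to_index[sb]))
            bond_orders[(i, j)] = order
    if bond_table is not None:
        bt = pd.read_csv(bond_table)
        for r in bt.itertuples():
            i, j = sorted((serial_to_index[int(r.serial_i)], serial_to_index[int(r.serial_j)]))
            bond_orders[(i, j)] = int(getattr(r, "order", 1))

    # distance-based completion within standard residues (and peptide links)
    coords = np.array([[a["x"], a["y"], a["z"]] for a in raw_atoms])
    for res in residues:
        if res.role not in ("protein", "water"):
            continue
        for i, j in itertools.combinations(res.atom_indices, 2):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            heavy = atoms[i].is_heavy and atoms[j].is_heavy
            cutoff = 1.9 if heavy else (1.3 if (atoms[i].is_heavy or atoms[j].is_heavy) else 0.0)
            if 0 < d < cutoff:
                bond_orders.setdefault((min(i, j), max(i, j)), 1)

    topo = Topology(
        atoms=atoms,
        residues=residues,
        bonds=sorted(bond_orders),
        bond_orders=bond_orders,
    )
    topo.dihedral_quads = _enumerate_dihedrals(topo)
    return topo


def _enumerate_dihedrals(topology: Topology) -> list[tuple[int, int, int, int]]:
    """One canonical dihedral per non-terminal heavy-atom protein bond."""
    heavy = {a.index for a in topology.atoms if a.is_heavy and a.role == "protein"}
    g = nx.Graph(topology.bonds)
    quads = []
    for b, c in topology.bonds:
        if b not in heavy or c not in heavy:
            continue
        a_nb = sorted(n for n in g.neighbors(b) if n != c and n in heavy)
        d_nb = sorted(n for n in g.neighbors(c) if n != b and n in heavy)
        if a_nb and d_nb:
            quads.append((a_nb[0], b, c, d_nb[0]))
    return quads


# ---------------------------------------------------------------------------
# Trajectory reading/writing
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, dt_sample: float = 2.0) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL) or concatenated XYZ ensemble."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return _read_xyz(path, dt_sample)
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    frames: list[np.ndarray] = []
    for frame_index, model in enumerate(structure.get_models()):
        coords = np.array([atom.coord for atom in model.get_atoms()], dtype=float)
        if coords.size == 0:
            raise TrajectoryError(f"{path}: frame {frame_index} has no atoms")
        if frames and coords.shape[0] != frames[0].shape[0]:
            raise TrajectoryError(
                f"{path}: frame {frame_index} has {coords.shape[0]} atoms, "
                f"expected {frames[0].shape[0]}"
            )
        frames.append(coords)
    if not frames:
        raise TrajectoryError(f"{path}: no coordinates found")
    return Trajectory(np.stack(frames), dt_sample)


def _read_xyz(path: Path, dt_sample: float) -> Trajectory:
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise TrajectoryError(f"{path}: frame {frame_index} truncated")
        coords = [[float(v) for v in ln.split()[1:4]] for ln in block]
        if frames and len(coords) != len(frames[0]):
            raise TrajectoryError(
                f"{path}: frame {frame_index} has {len(coords)} atoms, expected {len(frames[0])}"
            )
        frames.append(coords)
        frame_index += 1
        i += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return Trajectory(np.array(frames, dtype=float), dt_sample)


def write_trajectory(traj: Trajectory, topology: Topology, path: str | Path) -> None:
    """Write a multi-model PDB; coordinates are rounded to PDB precision (3 dp)."""
    path = Path(path)
    role_to_record = {"protein": "ATOM  ", "ligand": "HETATM", "water": "HETATM", "ion": "HETATM"}
    with path.open("w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for a in topology.atoms:
                res = topology.residues[a.residue_id]
                x, y, z = traj.frames[m, a.index]
                fh.write(
                    f"{role_to_record[a.role]}{a.serial:5d} {a.name:^4.4s} "
                    f"{res.label:>3.3s} A{a.residue_id + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{a.element.upper():>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# ΔG tables
# ---------------------------------------------------------------------------

def read_dg_table(csv_path: str | Path) -> list[DGRecord]:
    """Read a binding free-energy CSV (columns ``complex_id, dg_exptl, ...``)."""
    df = pd.read_csv(csv_path)
    if df.empty:
        return []
    if "complex_id" not in df.columns or "dg_exptl" not in df.columns:
        raise ValueError(f"{csv_path}: needs complex_id and dg_exptl columns")
    dupes = df["complex_id"][df["complex_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{csv_path}: duplicate complex_id {dupes.iloc[0]!r}")
    records = []
    extra_cols = [c for c in df.columns if c not in ("complex_id", "dg_exptl", "docking_score")]
    for row in df.itertuples():
        feats = {c: getattr(row, c) for c in extra_cols}
        ds = getattr(row, "docking_score", None)
        records.append(
            DGRecord(
                complex_id=str(row.complex_id),
                dg_exptl=float(row.dg_exptl),
                features=feats,
                docking_score=None if ds is None or pd.isna(ds) else float(ds),
            )
        )
    return records


def write_dg_table(records: Sequence[DGRecord], csv_path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {"complex_id": rec.complex_id, "dg_exptl": rec.dg_exptl}
        row.update({k: v for k, v in rec.features.items() if np.isscalar(v)})
        if rec.docking_score is not None:
            row["docking_score"] = rec.docking_score
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)
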
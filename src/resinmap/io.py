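"""Structures, trajectories, selections and descriptor-scale files.

The on-disk formats are the field's standard ones: PDB for structures,
multi-model PDB (plus XTC/DCD) for trajectories, CSV for residue descriptor
scales, TSV for tabular analysis output. PDB parsing and writing go through
biotite; binary trajectory formats go through mdtraj.

Residue identity throughout the package is the pair ``(chain_id, res_id)``
with 1-based PDB numbering. Insertion codes are rejected: the analysis
treats residue ids as unambiguous keys.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import ATOMIC_MASS

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class StructureError(ValueError):
    """Malformed or unsupported structural input."""


ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    res_index: int
    res_name: str
    chain_id: str

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_index)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Structure:
    """A protein (plus ligand) structure: an atom roster with coordinates.

    ``coords`` is an (n_atoms, 3) float array in Å, row-aligned with
    ``atoms``. Residues are keyed by ``(chain_id, res_index)``.
    """

    atoms: list[Atom]
    coords: np.ndarray
    ligand_resnames: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates in structure")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate atom ids in structure")
        allowed = set(STANDARD_RESIDUES) | set(self.ligand_resnames)
        bad = {a.res_name for a in self.atoms} - allowed
        if bad:
            raise StructureError(
                f"residue names {sorted(bad)} are neither standard amino acids "
                f"nor declared ligand residues"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_keys(self, protein_only: bool = False) -> list[ResidueKey]:
        """Residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            if protein_only and a.res_name in self.ligand_resnames:
                continue
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_name(self, key: ResidueKey) -> str:
        for a in self.atoms:
            if a.residue_key == key:
                return a.res_name
        raise KeyError(f"residue {key} not in structure")

    def atom_indices_of_residue(self, key: ResidueKey, heavy_only: bool = True) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_key == key and not (heavy_only and a.is_hydrogen)
        ]
        return np.asarray(idx, dtype=int)


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed atom roster, with per-frame boxes.

    ``coords`` is (n_frames, n_atoms, 3) in Å; ``box`` is (n_frames, 3)
    orthorhombic edge lengths in Å. ``dt_ps`` is the frame spacing where the
    source format records one.
    """

    structure: Structure
    coords: np.ndarray
    box: np.ndarray
    dt_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.structure.n_atoms:
            raise StructureError(
                f"trajectory coordinates have shape {self.coords.shape}; expected "
                f"(n_frames, {self.structure.n_atoms}, 3)"
            )
        if self.coords.shape[0] < 1:
            raise StructureError("trajectory must contain at least one frame")
        if self.box.shape != (self.n_frames, 3):
            raise StructureError(
                f"box array shape {self.box.shape} != ({self.n_frames}, 3)"
            )
        if not (self.box > 0).all():
            raise StructureError("box edge lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SelectionSpec:
    """Names a set of atoms, either explicitly or by (residue name, atom names).

    With ``heavy_only`` set (the default), hydrogens are dropped after
    resolution; the contact definition uses only non-hydrogen ligand atoms.
    """

    name: str
    atom_ids: tuple[int, ...] | None = None
    res_name: str | None = None
    atom_names: tuple[str, ...] | None = None
    heavy_only: bool = True

    def resolve(self, structure: Structure) -> np.ndarray:
        """Indices (into the structure's atom list) of the selected atoms."""
        if self.atom_ids is not None:
            wanted = set(self.atom_ids)
            idx = [i for i, a in enumerate(structure.atoms) if a.atom_id in wanted]
        elif self.res_name is not None:
            names = set(self.atom_names) if self.atom_names else None
            idx = [
                i
                for i, a in enumerate(structure.atoms)
                if a.res_name == self.res_name and (names is None or a.name in names)
            ]
        else:
            raise StructureError(f"selection {self.name!r} specifies no atoms")
        if self.heavy_only:
            idx = [i for i in idx if not structure.atoms[i].is_hydrogen]
        if not idx:
            raise StructureError(f"selection {self.name!r} resolves to zero atoms")
        return np.asarray(idx, dtype=int)


# --------------------------------------------------------------------------
# PDB structure / trajectory I/O (biotite-backed)
# --------------------------------------------------------------------------

def _infer_element(atom_name: str, given: str) -> str:
    if given and given.strip():
        return given.strip().upper()
    # PDB convention: columns 13-14 carry the element for standard names;
    # strip digits and take the leading letter(s)
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2].upper() in ATOMIC_MASS and not stripped[:1].upper() == "C":
        return stripped[:2].upper()
    return stripped[0].upper()


def _atom_array_to_structure(arr, ligand_resnames) -> Structure:
    if any(code.strip() for code in arr.ins_code):
        raise StructureError(
            "insertion codes are not supported; residue ids must be unambiguous"
        )
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                atom_id=int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else i + 1,
                name=str(arr.atom_name[i]),
                element=_infer_element(str(arr.atom_name[i]), str(arr.element[i])),
                res_index=int(arr.res_id[i]),
                res_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
            )
        )
    return Structure(atoms=atoms, coords=arr.coord.copy(), ligand_resnames=frozenset(ligand_resnames))


def _box_matrix_to_edges(box: np.ndarray) -> np.ndarray:
    off = box - np.diag(np.diagonal(box))
    if np.abs(off).max() > 1e-3:
        raise StructureError(
            "triclinic boxes are not supported; only orthorhombic (cubic) boxes"
        )
    return np.diagonal(box).copy()


def _read_pdb_file(path):
    from biotite.structure.io.pdb import PDBFile

    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc


def read_structure(path, ligand_resnames=()) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model if several).

    ``ligand_resnames`` declares non-amino-acid residue names that are
    legitimate (the resin-fragment ligand); anything else unrecognised is an
    error.
    """
    pdb = _read_pdb_file(path)
    try:
        arr = pdb.get_structure(model=1)
    except Exception as exc:
        raise StructureError(f"malformed coordinate records in {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError(f"{path} contains no atoms")
    return _atom_array_to_structure(arr, ligand_resnames)


def read_trajectory(
    topology_path,
    frames_path=None,
    ligand_resnames=(),
    box_edges=None,
    dt_ps: float | None = None,
) -> Trajectory:
    """Read a trajectory: a multi-model PDB, or a topology PDB + XTC/DCD.

    If only ``topology_path`` is given it must be a multi-model PDB whose
    models are the frames. ``box_edges`` supplies orthorhombic edge lengths
    (Å) when the trajectory carries no box.
    """
    structure = read_structure(topology_path, ligand_resnames)
    if frames_path is None:
        pdb = _read_pdb_file(topology_path)
        stack = pdb.get_structure(model=None)
        coords = np.atleast_3d(stack.coord)
        if coords.ndim == 2:
            coords = coords[None]
        boxes = stack.box
        if boxes is None:
            if box_edges is None:
                raise StructureError(
                    f"{topology_path} has no CRYST1 box; supply box_edges explicitly"
                )
            box = np.tile(np.asarray(box_edges, float), (coords.shape[0], 1))
        else:
            boxes = np.atleast_3d(boxes)
            box = np.stack([_box_matrix_to_edges(b) for b in boxes])
            if box.shape[0] == 1 and coords.shape[0] > 1:
                box = np.tile(box, (coords.shape[0], 1))
        return Trajectory(structure, coords, box, dt_ps=dt_ps)

    import mdtraj

    traj = mdtraj.load(str(frames_path), top=str(topology_path))
    if traj.n_atoms != structure.n_atoms:
        raise StructureError(
            f"atom count mismatch: topology has {structure.n_atoms} atoms, "
            f"trajectory frames have {traj.n_atoms}"
        )
    coords = traj.xyz.astype(float) * 10.0  # nm -> Å
    if traj.unitcell_lengths is not None:
        if traj.unitcell_angles is not None and np.abs(traj.unitcell_angles - 90.0).max() > 1e-2:
            raise StructureError("triclinic boxes are not supported")
        box = traj.unitcell_lengths.astype(float) * 10.0
    elif box_edges is not None:
        box = np.tile(np.asarray(box_edges, float), (traj.n_frames, 1))
    else:
        raise StructureError(
            f"{frames_path} carries no box information; supply box_edges"
        )
    if dt_ps is None and traj.timestep:
        dt_ps = float(traj.timestep)
    return Trajectory(structure, coords, box, dt_ps=dt_ps)


def _structure_to_atom_array(structure: Structure, coords=None, b_factor=None):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, dtype=np.float32)
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.res_id = np.array([a.res_index for a in structure.atoms])
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([a.res_name in structure.ligand_resnames for a in structure.atoms])
    arr.set_annotation("b_factor", np.asarray(b_factor if b_factor is not None else np.zeros(n), dtype=float))
    return arr


def write_structure(structure: Structure, path, b_factor=None) -> None:
    """Write a single-model PDB (coordinates at standard 3-decimal precision)."""
    from biotite.structure.io.pdb import PDBFile

    arr = _structure_to_atom_array(structure, b_factor=b_factor)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB with a CRYST1 box record."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = []
    for i in range(traj.n_frames):
        arr = _structure_to_atom_array(traj.structure, coords=traj.coords[i])
        frames.append(arr)
    stack = struc.stack(frames)
    stack.box = np.stack([np.diag(traj.box[i]) for i in range(traj.n_frames)])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_occupancy_pdb(structure: Structure, profile, path) -> None:
    """Export a PDB whose B-factor column is 100 × fractional occupancy.

    Residues absent from the profile get B = 0. The file is loadable by any
    molecular viewer for occupancy colouring.
    """
    occ = profile.occupancy if hasattr(profile, "occupancy") else dict(profile)
    for key, f in occ.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"occupancy {f} for residue {key} outside [0, 1]")
    b = np.zeros(structure.n_atoms)
    for i, a in enumerate(structure.atoms):
        if a.residue_key in occ:
            b[i] = 100.0 * occ[a.residue_key]
    write_structure(structure, path, b_factor=b)


def read_occupancy_pdb(path, ligand_resnames=()) -> dict[ResidueKey, float]:
    """Recover per-residue occupancy from a B-factor-encoded PDB."""
    pdb = _read_pdb_file(path)
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    occ: dict[ResidueKey, float] = {}
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]))
        occ[key] = float(arr.b_factor[i]) / 100.0
    return occ


# --------------------------------------------------------------------------
# Descriptor scale CSV I/O
# --------------------------------------------------------------------------

def read_scale_csv(path, name: str | None = None):
    """Read a residue descriptor scale: CSV with columns (code, value).

    Codes may be 1- or 3-letter; comment lines start with '#'. The file must
    define all 20 standard residues exactly once.
    """
    from .descriptors import DescriptorScale

    df = pd.read_csv(path, comment="#", header=None, names=["code", "value"],
                     skipinitialspace=True, dtype=str)
    # tolerate a header row
    if df.iloc[0]["code"].strip().lower() in {"code", "residue", "res"}:
        df = df.iloc[1:]
    values: dict[str, float] = {}
    for _, row in df.iterrows():
        code = str(row["code"]).strip().upper()
        if len(code) == 1:
            if code not in ONE_TO_THREE:
                raise StructureError(f"unknown 1-letter residue code {code!r}")
            code = ONE_TO_THREE[code]
        if code not in STANDARD_RESIDUES:
            raise StructureError(f"unknown residue code {code!r} in {path}")
        if code in values:
            raise StructureError(f"duplicate residue {code} in {path}")
        try:
            values[code] = float(row["value"])
        except (TypeError, ValueError):
            raise StructureError(
                f"non-numeric value {row['value']!r} for residue {code} in {path}"
            ) from None
    missing = [r for r in STANDARD_RESIDUES if r not in values]
    if missing:
        raise StructureError(f"scale file {path} missing residues: {', '.join(missing)}")
    scale_name = name if name is not None else Path(path).stem
    return DescriptorScale(name=scale_name, values=values)


def write_scale_csv(scale, path) -> None:
    """Write a descriptor scale as a (code, value) CSV."""
    with open(path, "w") as fh:
        fh.write(f"# descriptor scale: {scale.name}\n")
        for res in STANDARD_RESIDUES:
            fh.write(f"{res},{scale.values[res]!r}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
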
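"""Per-residue ligand contact occupancy, interaction surfaces and SASA.

The contact definition follows mixed-solvent MD practice for multimodal
chromatography ligands: a residue is "in contact" in a frame when the
mass-weighted centre of the ligand headgroup's heavy atoms lies strictly
within a cutoff (default 4 Å) of any heavy atom of the residue, under the
minimum-image convention for the orthorhombic simulation box. Fractional
occupancy f_r is the fraction of frames in contact; the interaction surface
is the residue set with f_r strictly above a threshold (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import ATOMIC_MASS, VDW_RADIUS
from .io import ResidueKey, SelectionSpec, Structure, Trajectory

DEFAULT_CUTOFF = 4.0     # Å, strict "less than"
DEFAULT_THRESHOLD = 0.05  # fractional occupancy, strict "above"


@dataclass
class ContactCounts:
    """Per-residue counts of frames (indicator mode) or ligand-copy contacts
    (summed mode) within the cutoff."""

    counts: dict[ResidueKey, int]
    n_frames: int
    n_copies: int = 1
    mode: str = "indicator"  # "indicator" | "summed"

    def __post_init__(self) -> None:
        cap = self.n_frames if self.mode == "indicator" else self.n_frames * self.n_copies
        for key, c in self.counts.items():
            if not (0 <= c <= cap):
                raise ValueError(
                    f"count {c} for residue {key} outside [0, {cap}] ({self.mode} mode)"
                )


@dataclass
class OccupancyProfile:
    """Fractional occupancy f_r = count / n_frames per residue."""

    occupancy: dict[ResidueKey, float]
    n_frames: int

    def __post_init__(self) -> None:
        for key, f in self.occupancy.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"occupancy {f} for residue {key} outside [0, 1]")


@dataclass
class InteractionSurface:
    """Residues with f_r strictly above the threshold, keeping their weights."""

    members: dict[ResidueKey, float]
    threshold: float
    res_names: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, f in self.members.items():
            if not f > self.threshold:
                raise ValueError(
                    f"residue {key} has f_r = {f} not above threshold {self.threshold}"
                )

    @property
    def n_residues(self) -> int:
        return len(self.members)


@dataclass
class ConvergenceSeries:
    """Cumulative occupancy vs frame plus a block-averaged standard error."""

    cumulative: np.ndarray
    block_means: np.ndarray
    block_sem: float

    @property
    def final_value(self) -> float:
        return float(self.cumulative[-1])


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def headgroup_center(
    frame_coords: np.ndarray, structure: Structure, headgroup: SelectionSpec
) -> np.ndarray:
    """Mass-weighted centre (Å) of the headgroup heavy atoms in one frame."""
    idx = headgroup.resolve(structure)
    masses = np.array([ATOMIC_MASS[structure.atoms[i].element.upper()] for i in idx])
    pts = np.asarray(frame_coords)[idx]
    return (masses[:, None] * pts).sum(axis=0) / masses.sum()


def minimum_image_distances(point: np.ndarray, coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Distances from *point* to each row of *coords* under the minimum-image
    convention for an orthorhombic box with edge lengths *box* (Å)."""
    delta = np.asarray(coords) - np.asarray(point)
    box = np.asarray(box, dtype=float)
    delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=-1))


def residue_min_distance(
    point: np.ndarray,
    frame_coords: np.ndarray,
    structure: Structure,
    residue: ResidueKey,
    box: np.ndarray,
) -> float:
    """Minimum-image distance (Å) from *point* to the nearest heavy atom of
    *residue*."""
    idx = structure.atom_indices_of_residue(residue, heavy_only=True)
    if idx.size == 0:
        raise ValueError(f"residue {residue} has no heavy atoms")
    return float(minimum_image_distances(point, np.asarray(frame_coords)[idx], box).min())


def frame_contacts(
    frame_coords: np.ndarray,
    structure: Structure,
    headgroups: SelectionSpec | list[SelectionSpec],
    box: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    residues: list[ResidueKey] | None = None,
) -> set[ResidueKey]:
    """Residues with any heavy atom strictly within *cutoff* of at least one
    headgroup centre in this frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(headgroups, SelectionSpec):
        headgroups = [headgroups]
    if residues is None:
        residues = structure.residue_keys(protein_only=True)
    centers = [headgroup_center(frame_coords, structure, hg) for hg in headgroups]
    out: set[ResidueKey] = set()
    for res in residues:
        idx = structure.atom_indices_of_residue(res, heavy_only=True)
        pts = np.asarray(frame_coords)[idx]
        for c in centers:
            if minimum_image_distances(c, pts, box).min() < cutoff:
                out.add(res)
                break
    return out


# --------------------------------------------------------------------------
# trajectory-level counting
# --------------------------------------------------------------------------

def _per_frame_contact_matrix(
    traj: Trajectory,
    headgroups: list[SelectionSpec],
    cutoff: float,
    residues: list[ResidueKey],
):
    """(n_frames, n_residues, n_copies) boolean contact array, vectorised over
    frames."""
    structure = traj.structure
    res_atom_idx = [structure.atom_indices_of_residue(r, heavy_only=True) for r in residues]
    n_frames = traj.n_frames
    contact = np.zeros((n_frames, len(residues), len(headgroups)), dtype=bool)
    for k, hg in enumerate(headgroups):
        idx = hg.resolve(structure)
        masses = np.array([ATOMIC_MASS[structure.atoms[i].element.upper()] for i in idx])
        centers = (
            masses[None, :, None] * traj.coords[:, idx, :]
        ).sum(axis=1) / masses.sum()  # (F, 3)
        for j, aidx in enumerate(res_atom_idx):
            delta = traj.coords[:, aidx, :] - centers[:, None, :]  # (F, A, 3)
            delta -= traj.box[:, None, :] * np.round(delta / traj.box[:, None, :])
            d2 = (delta**2).sum(axis=-1)  # (F, A)
            contact[:, j, k] = d2.min(axis=1) < cutoff**2
    return contact


def interaction_counts(
    traj: Trajectory,
    headgroups: SelectionSpec | list[SelectionSpec],
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "indicator",
) -> ContactCounts:
    """Per-residue interaction counts over a trajectory.

    ``mode="indicator"`` (default, used downstream) counts frames where at
    least one ligand copy contacts the residue, so counts/n_frames is a
    probability. ``mode="summed"`` adds one per contacting copy, a diagnostic
    for multi-copy runs.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    if mode not in ("indicator", "summed"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if isinstance(headgroups, SelectionSpec):
        headgroups = [headgroups]
    residues = traj.structure.residue_keys(protein_only=True)
    contact = _per_frame_contact_matrix(traj, headgroups, cutoff, residues)
    if mode == "indicator":
        per_res = contact.any(axis=2).sum(axis=0)
    else:
        per_res = contact.sum(axis=(0, 2))
    return ContactCounts(
        counts={r: int(c) for r, c in zip(residues, per_res)},
        n_frames=traj.n_frames,
        n_copies=len(headgroups),
        mode=mode,
    )


def contact_indicator_series(
    traj: Trajectory,
    headgroups: SelectionSpec | list[SelectionSpec],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Per-frame any-copy contact indicators; columns are residue keys."""
    if isinstance(headgroups, SelectionSpec):
        headgroups = [headgroups]
    residues = traj.structure.residue_keys(protein_only=True)
    contact = _per_frame_contact_matrix(traj, headgroups, cutoff, residues).any(axis=2)
    return pd.DataFrame(contact, columns=pd.Index(residues, tupleize_cols=False))


def occupancy_profile(counts: ContactCounts) -> OccupancyProfile:
    """f_r = interaction count / total frames."""
    if counts.n_frames < 1:
        raise ValueError("need at least one frame")
    return OccupancyProfile(
        occupancy={r: c / counts.n_frames for r, c in counts.counts.items()},
        n_frames=counts.n_frames,
    )


def relative_occupancy(profile: OccupancyProfile) -> dict[ResidueKey, float]:
    """Occupancy normalised to the highest-binding residue (max maps to 1)."""
    fmax = max(profile.occupancy.values(), default=0.0)
    if fmax <= 0:
        raise ValueError("all occupancies are zero; relative occupancy undefined")
    return {r: f / fmax for r, f in profile.occupancy.items()}


def interaction_surface(
    profile: OccupancyProfile,
    threshold: float = DEFAULT_THRESHOLD,
    structure: Structure | None = None,
) -> InteractionSurface:
    """Residues with f_r strictly above *threshold*, carrying their weights."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    members = {r: f for r, f in profile.occupancy.items() if f > threshold}
    names = {}
    if structure is not None:
        names = {r: structure.residue_name(r) for r in members}
    return InteractionSurface(members=members, threshold=threshold, res_names=names)


def convergence_series(indicator: np.ndarray, n_blocks: int) -> ConvergenceSeries:
    """Cumulative occupancy and block-averaged SEM for one residue's
    per-frame contact indicator.

    The block SEM — sample SD of the ``n_blocks`` block means over
    √n_blocks — estimates the standard error of the full-trajectory mean in
    the presence of frame-to-frame correlation, provided blocks are long
    relative to the correlation time.
    """
    x = np.asarray(indicator, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks for a standard error")
    n = x.size
    if n < n_blocks:
        raise ValueError(f"{n} frames cannot be split into {n_blocks} blocks")
    cumulative = np.cumsum(x) / np.arange(1, n + 1)
    # equal blocks; trailing remainder frames go to the last block
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    block_means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    sem = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    return ConvergenceSeries(cumulative=cumulative, block_means=block_means, block_sem=sem)


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

def solvent_exposed_residues(
    structure: Structure, probe: float = 1.4, n_points: int = 960
) -> set[ResidueKey]:
    """Residues with per-residue SASA > 0 on the reference structure
    (reported for coverage; counting is never filtered by this set)."""
    per_res = residue_sasa(structure, probe=probe, n_points=n_points)
    return {r for r, a in per_res.items() if a > 0.0}


def residue_sasa(
    structure: Structure, probe: float = 1.4, n_points: int = 960
) -> dict[ResidueKey, float]:
    """Shrake-Rupley accessible area (Å²) per residue, heavy atoms only,
    evaluated in the context of the whole structure."""
    import biotite.structure as struc

    heavy = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
    arr = struc.AtomArray(len(heavy))
    arr.coord = structure.coords[heavy].astype(np.float32)
    arr.element = np.array([structure.atoms[i].element for i in heavy])
    arr.atom_name = np.array([structure.atoms[i].name for i in heavy])
    arr.res_name = np.array([structure.atoms[i].res_name for i in heavy])
    arr.res_id = np.array([structure.atoms[i].res_index for i in heavy])
    arr.chain_id = np.array([structure.atoms[i].chain_id for i in heavy])
    radii = np.array([VDW_RADIUS[structure.atoms[i].element.upper()] for i in heavy])
    areas = struc.sasa(
        arr, probe_radius=probe, point_number=n_points, vdw_radii=radii,
        ignore_ions=False,
    )
    out: dict[ResidueKey, float] = {}
    for pos, i in enumerate(heavy):
        key = structure.atoms[i].residue_key
        out[key] = out.get(key, 0.0) + float(np.nan_to_num(areas[pos]))
    return out


def surface_sasa(
    structure: Structure,
    surface: InteractionSurface,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Total accessible area (Å²) of the interaction-surface residues,
    computed on the whole protein (neighbouring residues occlude)."""
    per_res = residue_sasa(structure, probe=probe, n_points=n_points)
    missing = [r for r in surface.members if r not in per_res]
    if missing:
        raise ValueError(f"surface residues absent from structure: {missing}")
    return float(sum(per_res[r] for r in surface.members))


# --------------------------------------------------------------------------
# tabular export
# --------------------------------------------------------------------------

def occupancy_table(
    structure: Structure, counts: ContactCounts, profile: OccupancyProfile
) -> pd.DataFrame:
    rows = []
    for res, c in counts.counts.items():
        rows.append(
            {
                "chain": res[0],
                "resindex": res[1],
                "resname": structure.residue_name(res),
                "count": c,
                "n_frames": counts.n_frames,
                "f_r": profile.occupancy[res],
            }
        )
    return pd.DataFrame(rows)


def surface_table(surface: InteractionSurface) -> pd.DataFrame:
    rows = [
        {
            "chain": r[0],
            "resindex": r[1],
            "resname": surface.res_names.get(r, ""),
            "f_r": f,
            "threshold": surface.threshold,
        }
        for r, f in sorted(surface.members.items())
    ]
    return pd.DataFrame(rows)
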
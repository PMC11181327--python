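import numpy as np
import pytest

from resinmap.io import Atom, SelectionSpec, Structure, Trajectory
from resinmap.synthetic import ContactScenario, emit_trajectory


@pytest.fixture
def tripeptide() -> Structure:
    """Three residues, one of them with a hydrogen, plus a 2-atom ligand."""
    atoms = [
        Atom(1, "CA", "C", 1, "ALA", "A"),
        Atom(2, "CB", "C", 1, "ALA", "A"),
        Atom(3, "CA", "C", 2, "GLY", "A"),
        Atom(4, "H1", "H", 2, "GLY", "A"),
        Atom(5, "CA", "C", 3, "ARG", "A"),
        Atom(6, "NH1", "N", 3, "ARG", "A"),
        Atom(7, "C1", "C", 4, "LIG", "L"),
        Atom(8, "O1", "O", 4, "LIG", "L"),
    ]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [10.0, 0.0, 0.0],
            [10.5, 0.8, 0.0],
            [20.0, 0.0, 0.0],
            [21.0, 1.0, 0.0],
            [5.0, 5.0, 0.0],
            [6.6, 5.0, 0.0],
        ]
    )
    return Structure(atoms=atoms, coords=coords, ligand_resnames=frozenset({"LIG"}))


@pytest.fixture
def headgroup() -> SelectionSpec:
    return SelectionSpec(name="headgroup", res_name="LIG", heavy_only=True)


@pytest.fixture
def small_scenario() -> ContactScenario:
    return ContactScenario(
        n_residues=5,
        p_bound=np.array([0.3, 0.2, 0.1, 0.05, 0.0]),
        tau=np.full(5, 4.0),
        n_frames=400,
        box_edge=100.0,
        seed=11,
    )


@pytest.fixture
def small_run(small_scenario):
    """(trajectory, ground-truth indicator table, headgroup) for a short run."""
    return emit_trajectory(small_scenario)


def random_geometry_trajectory(n_frames: int, n_residues: int, seed: int,
                               box_edge: float = 25.0) -> tuple[Trajectory, SelectionSpec]:
    """Trajectory with uniformly random protein and ligand coordinates in a
    small periodic box — a stress case where contacts arise only by chance
    and periodic wrapping matters."""
    rng = np.random.default_rng(seed)
    atoms = []
    aid = 1
    from resinmap.io import STANDARD_RESIDUES

    for r in range(n_residues):
        for name in ("CA", "CB"):
            atoms.append(
                Atom(aid, name, "C", r + 1, STANDARD_RESIDUES[r % 20], "A")
            )
            aid += 1
    atoms.append(Atom(aid, "C1", "C", n_residues + 1, "LIG", "L"))
    atoms.append(Atom(aid + 1, "O1", "O", n_residues + 1, "LIG", "L"))
    n_atoms = len(atoms)
    coords = rng.uniform(0, box_edge, size=(n_frames, n_atoms, 3))
    structure = Structure(
        atoms=atoms, coords=coords[0], ligand_resnames=frozenset({"LIG"})
    )
    traj = Trajectory(structure, coords, np.full((n_frames, 3), box_edge))
    return traj, SelectionSpec(name="headgroup", res_name="LIG", heavy_only=True)


def brute_force_counts(traj: Trajectory, headgroup: SelectionSpec,
                       cutoff: float = 4.0) -> dict:
    """Independent O(frames × atoms × 27 images) contact-count oracle: mass
    centre per frame, explicit enumeration of all 27 periodic images."""
    from resinmap.elements import ATOMIC_MASS

    structure = traj.structure
    idx = headgroup.resolve(structure)
    masses = np.array([ATOMIC_MASS[structure.atoms[i].element] for i in idx])
    residues = structure.residue_keys(protein_only=True)
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    counts = {r: 0 for r in residues}
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        box = traj.box[f]
        center = (masses[:, None] * frame[idx]).sum(axis=0) / masses.sum()
        for r in residues:
            aidx = structure.atom_indices_of_residue(r, heavy_only=True)
            hit = False
            for a in aidx:
                for s in shifts:
                    d = np.linalg.norm(frame[a] + s * box - center)
                    if d < cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                counts[r] += 1
    return counts
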
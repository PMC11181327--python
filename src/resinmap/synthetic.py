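"""Synthetic ground-truth generators for every pipeline stage.

Real inputs to this package are microsecond MD trajectories of a resin
fragment diffusing around a protein — expensive to produce and absent from
public deposition. These generators emulate the statistical structure of
those data with known ground truth:

* toy protein structures with well-separated residues,
* two-state (bound/unbound) Markov contact processes with prescribed
  stationary occupancies and correlation times,
* trajectories whose ligand placement realises a given contact series
  unambiguously under the 4 Å cutoff,
* multi-protein descriptor/elution datasets drawn from a known linear model
  with Gaussian noise.

Correlation-time convention: a chain with relaxation time τ (frames) keeps
its state with probability λ = 1 − 1/τ per step and otherwise redraws from
the stationary law, so the indicator autocorrelation is λ^k ≈ exp(−k/τ) for
large τ and τ = 1 gives exactly independent frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import STANDARD_RESIDUES, Atom, SelectionSpec, Structure, Trajectory

LIGAND_RESNAME = "LIG"
BOUND_DISTANCE = 3.0    # Å, safely inside the strict 4 Å cutoff
UNBOUND_MIN_DISTANCE = 8.0  # Å, safely outside
OTHER_MIN_DISTANCE = 6.0    # Å, clearance from non-bound residues


@dataclass
class ContactScenario:
    """A toy structure plus per-residue target occupancies p_r and
    correlation times τ_r (frames) for the contact process."""

    n_residues: int
    p_bound: np.ndarray          # per-residue stationary occupancy
    tau: np.ndarray              # per-residue correlation time, frames
    n_frames: int
    box_edge: float
    seed: int
    exclusive: bool = True       # single ligand: at most one residue bound/frame

    def __post_init__(self) -> None:
        self.p_bound = np.asarray(self.p_bound, dtype=float)
        self.tau = np.broadcast_to(np.asarray(self.tau, dtype=float),
                                   (self.n_residues,)).copy()
        if self.p_bound.shape != (self.n_residues,):
            raise ValueError("p_bound must have one entry per residue")
        if ((self.p_bound < 0) | (self.p_bound > 1)).any():
            raise ValueError("occupancies must lie in [0, 1]")
        if (self.tau < 1).any():
            raise ValueError("correlation times must be ≥ 1 frame")
        if self.exclusive and self.p_bound.sum() > 1.0 + 1e-12:
            raise ValueError(
                "exclusive (single-ligand) scenario needs Σ p_r ≤ 1 so that at "
                "most one residue is bound per frame"
            )
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class ElutionScenario:
    """Ground truth for a multi-protein descriptor/elution dataset.

    Defaults emulate a small multimodal-chromatography protein panel: the
    response spans roughly 0.2-1.4 mol/L NaCl (the experimental span for
    this resin runs from 0.27 to 1.32 M) and the noise sd is about 5% of
    the response spread.
    """

    beta0: float = 0.55
    beta_af: float = 0.45
    beta_hkd: float = 0.22
    sigma: float = 0.0123          # mol/L
    n_proteins: int = 6
    af_range: tuple[float, float] = (0.2, 1.4)
    hkd_range: tuple[float, float] = (-2.0, 1.0)
    n_nuisance: int = 13
    nuisance_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sd must be ≥ 0")
        if self.n_proteins < 4:
            raise ValueError("need at least 4 proteins")
        if not (0 <= self.nuisance_correlation < 1):
            raise ValueError("nuisance correlation must lie in [0, 1)")


def make_toy_structure(n_residues: int, seed: int = 0) -> Structure:
    """Toy protein: residues evenly spaced on a circle of radius
    max(15, 3·n) Å, three heavy atoms each, names cycling through the 20
    standard residues. Spacing guarantees no residue pair can both lie
    within 4 Å of one ligand position. Deterministic given the seed (the
    seed jitters atom geometry within each residue only)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    radius = max(15.0, 3.0 * n_residues)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    atom_id = 1
    names = ("CA", "CB", "CG")
    elements = ("C", "C", "C")
    for r in range(n_residues):
        angle = 2 * np.pi * r / n_residues
        center = radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        res_name = STANDARD_RESIDUES[r % len(STANDARD_RESIDUES)]
        # small deterministic jitter keeps residues non-degenerate
        offsets = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.4], [0.0, 1.2, -0.4]])
        offsets = offsets + 0.1 * rng.standard_normal((3, 3))
        for name, elem, off in zip(names, elements, offsets):
            atoms.append(
                Atom(atom_id=atom_id, name=name, element=elem,
                     res_index=r + 1, res_name=res_name, chain_id="A")
            )
            coords.append(center + off)
            atom_id += 1
    return Structure(atoms=atoms, coords=np.array(coords),
                     ligand_resnames=frozenset({LIGAND_RESNAME}))


def simulate_two_state(p_bound: float, tau: float, n_frames: int, seed: int) -> np.ndarray:
    """Stationary two-state Markov chain with P(bound) = p_bound and
    relaxation time τ frames (λ = 1 − 1/τ; τ = 1 → iid). Initialised from
    stationarity; boolean array of length n_frames."""
    if not (0.0 <= p_bound <= 1.0):
        raise ValueError("p_bound must lie in [0, 1]")
    if tau < 1:
        raise ValueError("tau must be ≥ 1")
    rng = np.random.default_rng(seed)
    lam = 1.0 - 1.0 / tau
    states = np.empty(n_frames, dtype=bool)
    # stay with prob lam, else redraw Bernoulli(p) — stationary by construction
    redraw = rng.random(n_frames) >= lam
    draws = rng.random(n_frames) < p_bound
    state = bool(rng.random() < p_bound)
    for i in range(n_frames):
        if redraw[i] or i == 0:
            state = bool(draws[i])
        states[i] = state
    return states


def _exclusive_state_sequence(scenario: ContactScenario, rng: np.random.Generator) -> np.ndarray:
    """Markov chain over {0 = unbound, 1..n = bound at residue i} with
    state-dependent holding probabilities λ_s = 1 − 1/τ_s and redraw
    distribution q_s ∝ π_s (1 − λ_s), which leaves the target stationary law
    π = (1 − Σp, p_1, ..., p_n) invariant."""
    p = scenario.p_bound
    pi = np.concatenate(([max(0.0, 1.0 - p.sum())], p))
    pi = pi / pi.sum()
    tau0 = float(scenario.tau.mean())
    tau = np.concatenate(([tau0], scenario.tau))
    lam = 1.0 - 1.0 / tau
    q = pi * (1.0 - lam)
    if q.sum() <= 0:
        raise ValueError("degenerate scenario: no state can be entered")
    q = q / q.sum()
    n = scenario.n_frames
    states = np.empty(n, dtype=np.int64)
    state = int(rng.choice(pi.size, p=pi))
    holds = rng.random(n)
    redraw_states = rng.choice(pi.size, size=n, p=q)
    for i in range(n):
        if i > 0 and holds[i] < lam[state]:
            pass  # hold current state
        else:
            state = int(redraw_states[i])
        states[i] = state
    return states


def emit_trajectory(scenario: ContactScenario) -> tuple[Trajectory, pd.DataFrame, SelectionSpec]:
    """Generate a trajectory realising a known contact process.

    Returns (trajectory, ground-truth per-frame indicator table with residue
    keys as columns, headgroup selection). When residue r is bound, the
    single-atom ligand headgroup sits 3.0 Å from r's first heavy atom
    (radially outward, so > 6 Å from every other residue); when unbound it
    sits at the ring centre, > 8 Å from everything.
    """
    structure = make_toy_structure(scenario.n_residues, scenario.seed)
    rng = np.random.default_rng(scenario.seed + 1)
    res_keys = structure.residue_keys(protein_only=True)

    if scenario.exclusive:
        seq = _exclusive_state_sequence(scenario, rng)
        indicators = np.zeros((scenario.n_frames, scenario.n_residues), dtype=bool)
        for r in range(scenario.n_residues):
            indicators[:, r] = seq == r + 1
    else:
        cols = []
        for r in range(scenario.n_residues):
            cols.append(
                simulate_two_state(
                    float(scenario.p_bound[r]), float(scenario.tau[r]),
                    scenario.n_frames, scenario.seed + 101 + r,
                )
            )
        indicators = np.column_stack(cols)

    # ligand: one carbon atom appended to the structure
    lig_atom = Atom(
        atom_id=structure.n_atoms + 1, name="C1", element="C",
        res_index=scenario.n_residues + 1, res_name=LIGAND_RESNAME, chain_id="L",
    )
    full_structure = Structure(
        atoms=structure.atoms + [lig_atom],
        coords=np.vstack([structure.coords, np.zeros(3)]),
        ligand_resnames=frozenset({LIGAND_RESNAME}),
    )

    box_edge = scenario.box_edge
    radius = max(15.0, 3.0 * scenario.n_residues)
    if box_edge < 2 * radius + 20.0:
        raise ValueError(
            f"box edge {box_edge} Å too small for the toy structure "
            f"(need ≥ {2 * radius + 20.0} Å clearance)"
        )
    shift = box_edge / 2.0  # centre the ring in the box
    anchor_idx = [structure.atom_indices_of_residue(k, heavy_only=True)[0] for k in res_keys]
    anchors = structure.coords[anchor_idx]  # (n_res, 3)
    out_dirs = anchors.copy()
    out_dirs[:, 2] = 0.0
    out_dirs /= np.linalg.norm(out_dirs, axis=1, keepdims=True)

    n_atoms = full_structure.n_atoms
    coords = np.empty((scenario.n_frames, n_atoms, 3))
    coords[:, : n_atoms - 1, :] = structure.coords[None] + shift
    bound_res = indicators.argmax(axis=1)
    any_bound = indicators.any(axis=1)
    lig = np.empty((scenario.n_frames, 3))
    lig[~any_bound] = shift  # ring centre
    if any_bound.any():
        idx = bound_res[any_bound]
        lig[any_bound] = anchors[idx] + BOUND_DISTANCE * out_dirs[idx] + shift
    coords[:, -1, :] = lig

    # verify the geometric contract on the distinct ligand sites
    all_heavy = structure.coords + shift
    res_of_atom = np.repeat(np.arange(scenario.n_residues), 3)
    for r in range(scenario.n_residues):
        site = anchors[r] + BOUND_DISTANCE * out_dirs[r] + shift
        d = np.linalg.norm(all_heavy - site, axis=1)
        if d[res_of_atom == r].min() > BOUND_DISTANCE + 1e-6:
            raise RuntimeError("bound-site placement lost its anchor distance")
        if d[res_of_atom != r].min() <= OTHER_MIN_DISTANCE:
            raise ValueError(
                "bound ligand site too close to a non-target residue; "
                "make_toy_structure spacing violated"
            )
    center_d = np.linalg.norm(all_heavy - shift, axis=1)
    if center_d.min() <= UNBOUND_MIN_DISTANCE:
        raise ValueError("unbound ligand site within 8 Å of the protein")

    box = np.full((scenario.n_frames, 3), box_edge)
    traj = Trajectory(full_structure, coords, box)
    truth = pd.DataFrame(indicators, columns=pd.Index(res_keys, tupleize_cols=False))
    headgroup = SelectionSpec(name="headgroup", res_name=LIGAND_RESNAME, heavy_only=True)
    return traj, truth, headgroup


def simulate_elution_dataset(scenario: ElutionScenario):
    """Draw a descriptor matrix and elution responses from a known linear
    model E = β₀ + β_AF·AF + β_HKD·HKD + N(0, σ²).

    AF and HKD are uniform over the scenario ranges; the remaining
    descriptors are Gaussian nuisance columns with pairwise correlation
    ``nuisance_correlation``, independent of AF and HKD. Returns
    (X, y, truth dict)."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_proteins
    af = rng.uniform(*scenario.af_range, size=n)
    hkd = rng.uniform(*scenario.hkd_range, size=n)
    m = scenario.n_nuisance
    rho = scenario.nuisance_correlation
    # equicorrelated Gaussians: shared factor + idiosyncratic part
    shared = rng.standard_normal(n)
    idio = rng.standard_normal((n, m))
    nuisance = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * idio
    noise = rng.normal(0.0, scenario.sigma, size=n)
    y = scenario.beta0 + scenario.beta_af * af + scenario.beta_hkd * hkd + noise
    data = {"AF": af, "HKD": hkd}
    for j in range(m):
        data[f"X{j + 1:02d}"] = nuisance[:, j]
    X = pd.DataFrame(data, index=[f"protein_{i + 1}" for i in range(n)])
    X.index.name = "protein"
    truth = {
        "beta0": scenario.beta0,
        "beta_AF": scenario.beta_af,
        "beta_HKD": scenario.beta_hkd,
        "sigma": scenario.sigma,
        "noise": noise,
    }
    return X, pd.Series(y, index=X.index, name="E"), truth


def protocol_summary(
    run_length_ns: float,
    save_interval_ps: float,
    n_runs: int = 1,
    n_replicas: int | None = None,
    replica_length_ns: float | None = None,
    box_edges: tuple[float, float] | None = None,
) -> dict:
    """Arithmetic of a simulation protocol: frames per run and aggregate,
    aggregate replica-exchange time, and box-volume ratios.

    All durations must be positive. Returns a plain dict for logging/JSON.
    """
    if run_length_ns <= 0 or save_interval_ps <= 0 or n_runs < 1:
        raise ValueError("durations and counts must be positive")
    frames_per_run = run_length_ns * 1000.0 / save_interval_ps
    out = {
        "frames_per_run": frames_per_run,
        "total_frames": frames_per_run * n_runs,
        "total_time_us": run_length_ns * n_runs / 1000.0,
    }
    if n_replicas is not None and replica_length_ns is not None:
        if n_replicas < 1 or replica_length_ns <= 0:
            raise ValueError("replica counts and lengths must be positive")
        out["aggregate_replica_time_us"] = n_replicas * replica_length_ns / 1000.0
    if box_edges is not None:
        a, b = box_edges
        if a <= 0 or b <= 0:
            raise ValueError("box edges must be positive")
        ratio = (a / b) ** 3
        out["box_volume_ratio"] = ratio
        out["box_volume_fold"] = round(ratio)
    return out
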
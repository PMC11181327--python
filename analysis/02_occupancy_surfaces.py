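#!/usr/bin/env python
"""Contact occupancy and interaction surfaces for the synthetic panel.

For each panel protein: per-residue counts and fractional occupancy f_r,
the interaction surface at the strict 5% rule, its summed SASA, a
convergence check (block SEM) for the top-binding residue, and an
occupancy-coloured PDB. Occupancies are also verified against the realised
ground-truth series — agreement is exact by construction, so any deviation
here flags a pipeline defect.

Reads results/panel/, writes results/occupancy/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from resinmap import contacts, io

PANEL = Path(__file__).resolve().parent.parent / "results" / "panel"
OUT = PANEL.parent / "occupancy"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = []
    for protein_dir in sorted(PANEL.iterdir()):
        if not (protein_dir / "trajectory.pdb").exists():
            continue
        name = protein_dir.name
        traj = io.read_trajectory(protein_dir / "trajectory.pdb",
                                  ligand_resnames=("LIG",))
        headgroup = io.SelectionSpec(name="headgroup", res_name="LIG")
        counts = contacts.interaction_counts(traj, headgroup)
        profile = contacts.occupancy_profile(counts)

        truth = io.read_tsv(protein_dir / "ground_truth.tsv")
        for col in truth.columns:
            chain, idx = col.split(":")
            realised = truth[col].mean()
            recovered = profile.occupancy[(chain, int(idx))]
            assert abs(recovered - realised) < 1e-12, (name, col)

        surface = contacts.interaction_surface(profile, 0.05,
                                               structure=traj.structure)
        sasa = contacts.surface_sasa(traj.structure, surface) if surface.n_residues else 0.0
        io.write_tsv(contacts.occupancy_table(traj.structure, counts, profile),
                     OUT / f"{name}_occupancy.tsv")
        io.write_tsv(contacts.surface_table(surface), OUT / f"{name}_surface.tsv")
        io.write_occupancy_pdb(traj.structure, profile, OUT / f"{name}_colored.pdb")

        ind = contacts.contact_indicator_series(traj, headgroup)
        top = max(profile.occupancy, key=profile.occupancy.get)
        conv = contacts.convergence_series(ind[top].to_numpy(), n_blocks=10)
        summary.append({
            "protein": name,
            "surface_residues": surface.n_residues,
            "surface_sasa_A2": sasa,
            "top_residue": f"{top[0]}:{top[1]}",
            "top_f_r": profile.occupancy[top],
            "top_block_sem": conv.block_sem,
        })
        print(f"{name}: surface N={surface.n_residues}, SASA={sasa:.1f} Å², "
              f"top f_r={profile.occupancy[top]:.3f} ± {conv.block_sem:.3f}")
    io.write_tsv(pd.DataFrame(summary), OUT / "summary.tsv")
    print(f"occupancy recovered exactly for all proteins; tables in {OUT}")


if __name__ == "__main__":
    main()
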
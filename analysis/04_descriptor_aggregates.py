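#!/usr/bin/env python
"""Occupancy-weighted descriptor aggregates for the synthetic panel.

Each protein's interaction surface is collapsed to one aggregate value per
descriptor scale (weighted average Σ f·d / Σ f): aromaphilicity AF,
hydrophobicity scales (Kyte-Doolittle HKD, Radzicka-Wolfenden HRW,
Eisenberg), Hopp-Woods hydrophilicity HHW, side-chain charge at pH 6, and
the arginine indicator (whose aggregate is the arginine occupancy score).

Reads results/occupancy/, writes results/descriptors/descriptor_matrix.tsv.
"""

from pathlib import Path

from resinmap import descriptors, io
from resinmap.contacts import InteractionSurface

OCC = Path(__file__).resolve().parent.parent / "results" / "occupancy"
OUT = OCC.parent / "descriptors"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    surfaces = {}
    for surf_file in sorted(OCC.glob("*_surface.tsv")):
        name = surf_file.name.removesuffix("_surface.tsv")
        tab = io.read_tsv(surf_file)
        if tab.empty:
            print(f"{name}: empty interaction surface, skipped")
            continue
        surfaces[name] = InteractionSurface(
            members={(r["chain"], int(r["resindex"])): float(r["f_r"])
                     for _, r in tab.iterrows()},
            threshold=float(tab["threshold"].iloc[0]),
            res_names={(r["chain"], int(r["resindex"])): r["resname"]
                       for _, r in tab.iterrows()},
        )
    dset = descriptors.default_descriptor_set(pH=6.0)
    mat = descriptors.descriptor_matrix(surfaces, dset)
    io.write_tsv(mat.reset_index(), OUT / "descriptor_matrix.tsv")
    print(mat.round(3).to_string())
    print(f"matrix written to {OUT / 'descriptor_matrix.tsv'}")


if __name__ == "__main__":
    main()
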
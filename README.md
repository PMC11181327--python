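# resinmap

Mixed-solvent molecular-dynamics analysis for multimodal chromatography:
from protein–ligand trajectories to per-residue binding occupancy,
interaction surfaces, occupancy-weighted physicochemical descriptors,
dissociation constants, and a linear model of the NaCl concentration a
protein needs to elute from a multimodal cation-exchange resin.

## Who this is for

Downstream-processing and biomolecular-simulation groups who run (or plan
to run) MD simulations of a resin-fragment ligand — e.g. a Capto MMC
headgroup — diffusing around a protein, and want to turn those trajectories
into chromatography-relevant quantities without hand-rolled scripts. The
package also ships a synthetic-data generator that emulates the statistical
structure of such trajectories with known ground truth, so the entire
pipeline is testable without running MD.

## The method

**Contact occupancy.** A residue *r* is in contact in a frame when the
mass-weighted centre of the ligand headgroup's heavy atoms lies strictly
within 4 Å (minimum-image convention) of any heavy atom of *r*. The
fractional occupancy *f_r* is the fraction of frames in contact, and the
**interaction surface** is the set of residues with *f_r* > 5%.

**Descriptor aggregates.** For a descriptor scale *d* (Kyte–Doolittle
hydrophobicity, aromaphilicity, Hopp–Woods hydrophilicity, side-chain
charge at pH 6, an arginine indicator, …) the per-protein aggregate is the
occupancy-weighted average over the N surface residues:

    d̄ = Σ_r f_r·d_r / Σ_r f_r

**Thermodynamics.** With a single ligand in a box of volume *v*, treating
each residue (or the whole protein) as a binding site with bound fraction
*P_b* = 1 − *P_u*:

    K_d = (P_u / P_b) · 1 / (N_av · v),    ΔG_b = R·T·ln(K_d / c⁰)

with *c⁰* = 1 mol/L. For *P_b* = 0.5 in a (100 Å)³ box, K_d = 1.66 mM —
the millimolar regime typical of resin-fragment binding. Uncertainty comes
from a moving-block bootstrap over frames.

**Elution model.** Elution salt concentration *E* (mol/L) is regressed on
the descriptor aggregates by forward stepwise selection with the
small-sample-corrected AICc as stopping rule:

    E = β₀ + β_AF·AF + β_HKD·HKD    (the two-predictor truth of the
                                     synthetic benchmark)

with leave-one-out validation and Kendall-τ rank concordance of predicted
vs observed elution order.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
six-protein synthetic panel (each "protein" is a toy structure whose
per-residue contact process is a two-state Markov chain with prescribed
occupancies):

```
python analysis/01_simulate_trajectories.py
python analysis/02_occupancy_surfaces.py
python analysis/03_thermodynamics.py
python analysis/04_descriptor_aggregates.py
python analysis/05_fit_elution_model.py
```

Representative output (stage 2 recovers the generator's realised
occupancies exactly; stage 3 prints per-protein global binding):

```
strong_arg: surface N=3, SASA=504.8 Å², top f_r=0.435 ± 0.034
weak_b:     surface N=2, SASA=326.6 Å², top f_r=0.099 ± 0.021
...
strong_arg: global P_b=0.732, K_d=0.61 mM [0.49, 0.75], ΔG=-18.47 kJ/mol, 77 binding events
weak_b:     global P_b=0.243, K_d=5.17 mM [4.16, 6.16], ΔG=-13.13 kJ/mol, 71 binding events
```

Here `top f_r` is the occupancy of the strongest-binding residue with its
block standard error; `K_d` is the global dissociation constant with its
95% bootstrap CI, smaller for stronger binders; `ΔG` is the corresponding
binding free energy. Stage 5 prints the stepwise trace (AICc, R², RMSE,
error degrees of freedom per step), the noiseless recovery of the true
coefficients (β exact to 1e-8), leave-one-out errors, and the rank
concordance (τ = 1.000, exact ordering) of the true-variable model. Note
that at n = 6 proteins the AICc penalty for additional variables is severe,
so the greedy selection frequently stops early at realistic noise — see
`docs/methods.md` for the small-sample analysis.

There is also a CLI for single runs on your own files:

```
resinmap occupancy --structure traj.pdb --outdir out/
resinmap thermo --structure traj.pdb --seed 1 --outdir out/
resinmap fit --descriptors matrix.tsv --elution observed.tsv --outdir out/
resinmap protocol-summary --run-length-ns 2000 --save-interval-ps 10
```

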
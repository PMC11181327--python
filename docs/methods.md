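# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `resinmap`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Contact definition and occupancy

A residue is in contact with the ligand in a frame when the mass-weighted
centre of the ligand headgroup's **heavy atoms** is strictly within a
cutoff (default 4.0 Å) of **any heavy atom** of the residue. Conventions:

- **Strict inequalities** at both the 4 Å cutoff and the 5% surface
  threshold ("less than", "above"). Both are configurable.
- **Minimum-image distances** under the orthorhombic box. The ligand
  diffuses freely, so periodic wrapping is required; triclinic boxes are
  rejected with an explicit error (the target use case is cubic boxes).
- **Mass-weighted centre**, not geometric: "centre of mass" is read
  literally, with masses from the packaged element table.
- **Multi-copy counting** defaults to the any-copy indicator so that
  count/n_frames stays a probability; a summed mode (one per contacting
  copy) is kept for diagnostics of multi-copy simulations.
- Headgroup-only contacts systematically underestimate the full-resin
  affinity (the linker and backbone are ignored). This is documented, not
  corrected.

"Solvent-exposed residue" is operationalised as per-residue SASA > 0 Å² on
the reference structure and used only for coverage reporting; counting is
never filtered by it, so a buried residue that becomes exposed during the
trajectory is not silently dropped.

Fractional occupancy is f_r = count / n_frames; relative occupancy
normalises to the highest-binding residue. The interaction surface carries
each member's f_r so downstream descriptor aggregation needs no second pass
over the trajectory.

### Convergence diagnostics

`convergence_series` reports the cumulative occupancy versus frame and a
block standard error: the series is cut into `n_blocks` equal blocks and
the SEM is the sample SD of block means over √n_blocks. This estimates the
standard error of the trajectory mean in the presence of frame-to-frame
correlation provided blocks are long relative to the correlation time; the
test suite validates it against the SD over 200 independent replicate
simulations (agreement within 30%).

### SASA

Solvent-accessible surface area uses the Shrake–Rupley algorithm (via
biotite) with probe radius 1.4 Å and 960 sphere points, Bondi element
radii, heavy atoms only, always evaluated in the context of the whole
structure so neighbouring residues occlude. An isolated sphere of radius
1.9 Å yields 4π(3.3)² = 136.85 Å² to well within the 2% quadrature
tolerance. The interaction-surface SASA is the sum of member-residue
SASAs; an occupancy-weighted variant can be formed from the per-residue
table if a merged-patch definition is preferred — both raw outputs are
reported rather than guessing a single convention.

## Descriptor scales and aggregation

Packaged scales: Kyte–Doolittle hydropathy (HKD), Radzicka–Wolfenden
transfer free energies (HRW; proline has no measured value and is set to
0.0 by convention), Eisenberg consensus hydrophobicity, Hopp–Woods
hydrophilicity (HHW), an aromaphilicity index (AF — a clearly labelled
**synthetic stand-in** ranking aromatics highest and Arg above Lys; replace
with a published residue-level scale via a user CSV for production use),
side-chain charge at pH (default 6.0, the simulation protonation
condition), and the arginine indicator. Additional hydrophobicity scales
load from two-column CSVs; the model-fitting stage accepts any scale set,
so the packaged set's completeness is not load-bearing.

**Charge rule.** Side chains are protonated iff pH ≤ pKa (ties protonate),
with packaged pKa values Asp 3.9, Glu 4.2, His 6.0, Cys 8.3, Tyr 10.1,
Lys 10.5, Arg 12.5; charges are integers in {−1, 0, +1}. At pH 6.0
histidine sits exactly at its pKa and is counted protonated (+1).

**Aggregation.** The per-protein aggregate is the normalised weighted
average d̄ = Σ f·d / Σ f — a true weighted mean, which is
affine-equivariant, permutation- and weight-splitting-invariant, bounded by
the member values, and reduces to the arithmetic mean under equal weights.
An unnormalised Σ f·d mode is available behind a flag for sensitivity
checks (dividing by N instead of Σf is a third convention; the normalised
form is the default because it alone is scale-location equivariant). The
arginine occupancy score (AOS) is the aggregate of the arginine indicator.

## Thermodynamics

With one ligand in a box of volume v (Å³, converted at 1 Å³ = 10⁻²⁷ L):

    K_d = (P_u / P_b) · 1/(N_av · v),   ΔG_b = R·T·ln(K_d / c⁰)

with c⁰ = 1 mol/L, R = 8.31446×10⁻³ kJ/(mol·K), default T = 300 K. This is
the standard single-molecule-in-a-box estimator; an alternative P_u²/P_b
form (appropriate when the unbound concentration itself is P_u/(N_av·v)) is
selectable and the choice is logged in outputs. P_b ∈ {0, 1} makes the
estimator undefined and raises a dedicated error; the CLI flags such sites
rather than failing.

**Events.** Binding/unbinding events are state transitions after
suppressing runs shorter than `min_dwell` frames (short runs are absorbed
into the preceding state; the first run is always kept). Default
min_dwell = 1, i.e. raw transitions.

**Bootstrap CIs.** Moving-block bootstrap, percentile 2.5/97.5 interval,
n_boot = 1000. Block length defaults to 20× the integrated autocorrelation
time of the bound-state series (initial-positive-sequence estimator, capped
at n/10), so correlated frames are resampled in coherent chunks. Known
behaviour: at the sizes used in the calibration experiment (iid frames,
P_b = 0.5, 5000 frames) the interval covers the analytic K_d in about
93–94% of repeats — the familiar small-sample undercoverage of percentile
intervals — which satisfies the ≥ 93% calibration check; materially shorter
series (≈1500 frames) drop to ≈92% and should not be trusted for
confidence statements at this block length.

## Elution model

OLS (via statsmodels) with R² = 1 − SSE/SST and RMSE = √(SSE/DFE),
DFE = n − p − 1 (the error-degrees-of-freedom convention of standard
stepwise-regression software; √(SSE/n) is available by flag). A condition
number above 10⁸ on the design matrix raises a rank-deficiency error —
deliberate, because highly correlated descriptor pairs (hydrophobicity vs
hydrophilicity scales) invite overfitting on small panels.

**AICc.** AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) with k = p + 2
(intercept, slopes, residual variance). The additive Gaussian constant
n·ln(2π) + n is dropped by default (it cancels in comparisons) and can be
included via `constant=True` for cross-checking against software that
reports full-likelihood AICc. SSE is floored at 10⁻¹² so perfect fits stay
finite.

**Stepwise.** Greedy forward selection: at each step add the variable whose
model minimises AICc; stop when no addition lowers AICc, when DFE would
drop below 1, or when AICc becomes undefined for the larger model
(n − k − 1 ≤ 0, which at n = 6 already happens at p = 3). Ties break toward
fewer variables, then lexicographic names, making the trace deterministic.

*Small-sample behaviour.* At n = 6 the AICc penalty steps are large: adding
the first variable costs 10 penalty units (requiring single-variable
R² > 0.81 to enter) and the second costs 30 (requiring the second variable
to remove > 99.3% of the remaining SSE). Consequently, at noise levels of a
few percent of the response spread, the greedy rule often stops at the null
or one-variable model even when the response is genuinely generated by two
descriptors — a property of AICc-stopped forward selection on six
observations, not a defect of the optimiser, and the reason panel sizes
this small support only very-low-noise model identification. The full
forward path (and the bidirectional variant) can still be inspected via the
returned trace.

**Validation.** Leave-one-out refits each fold and reports the held-out
prediction error, which equals the closed-form PRESS residual
e_i/(1 − h_ii); rank concordance is Kendall τ with an exact-order flag
(τ = 1). Model coefficients are never shipped as constants: the model is
always refit from supplied data.

## Synthetic data

The generators define the study conditions for every statistical check.

- `make_toy_structure(n)`: residues evenly spaced on a circle of radius
  max(15, 3n) Å, three carbon atoms each, names cycling through the 20
  standard residues; inter-residue spacing always exceeds 8 Å so no ligand
  position can contact two residues at the 4 Å cutoff.
- `simulate_two_state(p, τ)`: stationary two-state Markov chain with
  P(bound) = p. Correlation-time convention: per step the chain holds its
  state with probability λ = 1 − 1/τ, otherwise redraws from the stationary
  law — so τ = 1 is exactly iid and the indicator autocorrelation is
  λ^k ≈ e^(−k/τ) for large τ. Chains are initialised from stationarity.
- `emit_trajectory`: realises a contact process geometrically — bound
  frames place the single-atom headgroup 3.0 Å from the target residue's
  anchor atom (> 6 Å from every other residue), unbound frames place it at
  the ring centre (> 8 Å from everything) — so recovered counts equal the
  realised state series *exactly*, and statistical error enters only
  through the chain itself. The single-ligand default enforces at most one
  bound residue per frame via a hold/redraw chain over
  {unbound, bound@r₁, …} with state-dependent holding probabilities
  λ_s = 1 − 1/τ_s and redraw weights q_s ∝ π_s(1 − λ_s), which leaves the
  prescribed stationary law exactly invariant; an overlapping mode
  (independent per-residue chains) exists for stress-testing the state
  machinery, with the geometric realisation then following the
  first-bound residue only.
- `simulate_elution_dataset`: E = β₀ + β_AF·AF + β_HKD·HKD + N(0, σ²) with
  AF ~ U(0.2, 1.4), HKD ~ U(−2, 1), defaults β = (0.55, 0.45, 0.22) and
  σ = 0.0123 mol/L (≈ 5% of the response SD), chosen so E spans roughly
  0.2–1.4 mol/L — the experimental span of NaCl elution concentrations on
  this resin chemistry. Thirteen nuisance descriptors are equicorrelated
  Gaussians (ρ = 0.3), independent of the true predictors, to exercise
  selection under realistic collinearity.

What the generators deliberately do **not** emulate: physically realistic
ligand diffusion paths, solvent, conformational protein motion, energy
terms, or correlated occupancy across residues beyond mutual exclusion.
Passing the closure tests therefore demonstrates the *analysis* is correct
and calibrated, not that any particular force field or sampling protocol
is adequate.

## Problem sizes used in the checks

Chosen to give each statistical check adequate resolution while keeping
the whole suite fast: 20,000 frames for occupancy closure (binomial SE
≈ 10⁻³ at p = 0.02); 5000-frame series × 300 repeats × 1000 resamples for
bootstrap calibration (shorter series measurably undercover, see above);
20 random geometries (≤ 100 frames, ≤ 30 residues) for exact brute-force
agreement; 200 replicates for the selection-rate and coverage experiments;
n = 24 for the parameter-recovery check. All randomised steps take explicit
seeds; there is no clock seeding anywhere.

## Known limitations

- Insertion codes, altlocs and triclinic boxes are rejected, not handled.
- The aromaphilicity scale shipped is a synthetic surrogate (see above).
- K_d assumes a single ligand copy; multi-copy trajectories should use the
  occupancy machinery only, or derive per-copy series upstream.
- Binding-event counts are raw transition counts; no kinetic model
  (k_on/k_off) is fitted.
- The SASA of an interaction surface is the sum over member residues; a
  merged-patch area would differ where members abut.
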
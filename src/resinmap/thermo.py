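"""Binding thermodynamics from bound/unbound frame fractions.

With a single ligand diffusing in a simulation box of volume v, treating
each residue (or the whole protein) as a binding site, the bound fraction
P_b of trajectory frames yields the single-molecule dissociation constant

    K_d = (P_u / P_b) · 1 / (N_av · v)        [v in litres]

and the binding free energy ΔG_b = R·T·ln(K_d / c⁰) with c⁰ = 1 mol/L.
Because only the ligand headgroup enters the contact definition (not the
linker or matrix backbone), the affinity is a lower bound on the full-resin
affinity; this is documented, not corrected.

Uncertainty on K_d comes from a moving-block bootstrap over frames, with
block length tied to the integrated autocorrelation time of the bound-state
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23          # 1/mol
GAS_CONSTANT_KJ = 8.31446e-3      # kJ/(mol·K)
STANDARD_CONC = 1.0               # mol/L
A3_TO_L = 1e-27                   # litres per Å³


class DegenerateEstimateError(ValueError):
    """Bound fraction is 0 or 1: the K_d estimator is undefined.

    Longer sampling (or a site that actually exchanges) is needed; a site
    never seen bound carries no affinity information, and a site always
    bound only bounds K_d from above.
    """


@dataclass
class BindingStateSeries:
    """Per-frame boolean bound state for one site ("global" = any residue)."""

    states: np.ndarray
    site: str
    dt_ps: float | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("state series must be a non-empty 1-D array")

    @property
    def n_frames(self) -> int:
        return self.states.size


@dataclass
class ThermoEstimate:
    site: str
    p_bound: float
    p_unbound: float
    kd: float                 # mol/L
    dg: float                 # kJ/mol
    temperature: float        # K
    box_volume_a3: float      # Å³
    ci_low: float | None = None
    ci_high: float | None = None
    n_binding_events: int | None = None
    n_unbinding_events: int | None = None
    estimator: str = "pu_over_pb"


def bound_state_series(
    frame_contacts: list[set],
    site,
    dt_ps: float | None = None,
) -> BindingStateSeries:
    """Build the per-frame bound indicator for *site*.

    *site* is a residue key, or the string ``"global"`` for bound-to-any-
    residue (the element-wise OR of all residue series).
    """
    if len(frame_contacts) < 1:
        raise ValueError("need at least one frame")
    if site == "global":
        states = np.array([len(s) > 0 for s in frame_contacts])
        label = "global"
    else:
        known = set().union(*frame_contacts) if frame_contacts else set()
        states = np.array([site in s for s in frame_contacts])
        if not states.any() and site not in known:
            # permitted (a residue may simply never bind) but flag impossible keys
            pass
        label = f"{site[0]}:{site[1]}" if isinstance(site, tuple) else str(site)
    return BindingStateSeries(states=states, site=label, dt_ps=dt_ps)


def bound_fractions(series: BindingStateSeries) -> tuple[float, float]:
    """(P_b, P_u): fractions of frames bound and unbound."""
    p_b = float(series.states.mean())
    return p_b, 1.0 - p_b


def kd_estimate(
    p_bound: float,
    p_unbound: float,
    box_volume_a3: float,
    estimator: str = "pu_over_pb",
) -> float:
    """Dissociation constant (mol/L) for one ligand in a box of volume
    *box_volume_a3* (Å³).

    ``estimator="pu_over_pb"`` is the default single-site form
    (P_u/P_b)/(N_av·v); ``"pu2_over_pb"`` uses P_u²/P_b, the form appropriate
    when the unbound-ligand concentration itself is P_u/(N_av·v).
    """
    if box_volume_a3 <= 0:
        raise ValueError("box volume must be positive")
    if not (0.0 < p_bound < 1.0):
        raise DegenerateEstimateError(
            f"P_b = {p_bound}: dissociation constant undefined for a site that "
            f"is never (or always) bound; extend sampling"
        )
    v_litres = box_volume_a3 * A3_TO_L
    if estimator == "pu_over_pb":
        ratio = p_unbound / p_bound
    elif estimator == "pu2_over_pb":
        ratio = p_unbound**2 / p_bound
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return ratio / (AVOGADRO * v_litres)


def binding_free_energy(kd: float, temperature: float = 300.0) -> float:
    """ΔG_b = R·T·ln(K_d/c⁰) in kJ/mol (negative for sub-molar K_d)."""
    if kd <= 0:
        raise ValueError("K_d must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KJ * temperature * np.log(kd / STANDARD_CONC)


def count_binding_events(series: BindingStateSeries, min_dwell: int = 1) -> tuple[int, int]:
    """(n_binding, n_unbinding) transitions after suppressing runs shorter
    than *min_dwell* frames.

    Short runs are merged into the preceding state (the first run is always
    kept), then unbound→bound and bound→unbound transitions are counted.
    Default min_dwell = 1 counts raw transitions.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be ≥ 1")
    x = series.states.astype(int)
    # run-length encode
    change = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    run_states = x[starts]
    run_lens = ends - starts
    if min_dwell > 1:
        merged: list[list[int]] = []  # [state, length]
        for s, ln in zip(run_states, run_lens):
            if not merged:
                merged.append([int(s), int(ln)])
            elif ln < min_dwell or s == merged[-1][0]:
                merged[-1][1] += int(ln)  # absorb short run into previous state
            else:
                merged.append([int(s), int(ln)])
        run_states = np.array([s for s, _ in merged])
    n_bind = int(((run_states[:-1] == 0) & (run_states[1:] == 1)).sum())
    n_unbind = int(((run_states[:-1] == 1) & (run_states[1:] == 0)).sum())
    return n_bind, n_unbind


def integrated_autocorrelation_time(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time τ_int = 1 + 2·Σ ρ_k, summing the
    initial positive sequence of autocorrelations (Geyer-style truncation),
    capped at len(x)/10."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return 1.0
    cap = max(1, n // 10)
    if max_lag is None:
        max_lag = cap
    tau = 1.0
    for k in range(1, min(max_lag, n - 1) + 1):
        rho = float(x[:-k] @ x[k:]) / ((n - k) * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return min(tau, float(cap))


def default_block_length(series: BindingStateSeries) -> int:
    """20 × integrated autocorrelation time, capped at n/10, floor 1."""
    tau = integrated_autocorrelation_time(series.states.astype(float))
    n = series.n_frames
    return int(max(1, min(round(20.0 * tau), n // 10 if n >= 10 else 1)))


def bootstrap_ci(
    series: BindingStateSeries,
    box_volume_a3: float,
    statistic: str = "kd",
    n_boot: int = 1000,
    block_len: int | None = None,
    seed: int | None = None,
    estimator: str = "pu_over_pb",
    temperature: float = 300.0,
) -> tuple[float, float]:
    """Moving-block bootstrap percentile 95% CI for K_d (or ΔG or P_b).

    Overlapping blocks of length *block_len* are resampled with replacement
    and concatenated to the original series length; the statistic is
    recomputed on each resample. Fails if the statistic is degenerate
    (P_b ∈ {0,1}) in more than half of the resamples.
    """
    if block_len is None:
        block_len = default_block_length(series)
    n = series.n_frames
    if n < 2 * block_len:
        raise ValueError(
            f"series length {n} is shorter than two blocks of {block_len}"
        )
    rng = np.random.default_rng(seed)
    x = series.states.astype(np.int8)
    n_blocks_per_sample = int(np.ceil(n / block_len))
    n_starts = n - block_len + 1
    starts = rng.integers(0, n_starts, size=(n_boot, n_blocks_per_sample))
    # gather blocks: (n_boot, n_blocks, block_len) -> flatten, truncate to n
    offsets = np.arange(block_len)
    idx = (starts[:, :, None] + offsets[None, None, :]).reshape(n_boot, -1)[:, :n]
    p_b = x[idx].mean(axis=1)
    ok = (p_b > 0) & (p_b < 1)
    if ok.sum() < n_boot / 2:
        raise DegenerateEstimateError(
            "bound fraction degenerate in most bootstrap resamples; series too "
            "short or too one-sided for a confidence interval"
        )
    p_b = p_b[ok]
    if statistic == "p_bound":
        vals = p_b
    else:
        v_litres = box_volume_a3 * A3_TO_L
        if estimator == "pu_over_pb":
            ratio = (1.0 - p_b) / p_b
        elif estimator == "pu2_over_pb":
            ratio = (1.0 - p_b) ** 2 / p_b
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        kd = ratio / (AVOGADRO * v_litres)
        if statistic == "kd":
            vals = kd
        elif statistic == "dg":
            vals = GAS_CONSTANT_KJ * temperature * np.log(kd / STANDARD_CONC)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def site_thermodynamics(
    series: BindingStateSeries,
    box_volume_a3: float,
    temperature: float = 300.0,
    estimator: str = "pu_over_pb",
    n_boot: int = 1000,
    block_len: int | None = None,
    seed: int | None = None,
    with_ci: bool = True,
) -> ThermoEstimate:
    """Full per-site estimate: fractions, K_d, ΔG, events and bootstrap CI."""
    p_b, p_u = bound_fractions(series)
    kd = kd_estimate(p_b, p_u, box_volume_a3, estimator=estimator)
    dg = binding_free_energy(kd, temperature)
    n_bind, n_unbind = count_binding_events(series)
    ci_low = ci_high = None
    if with_ci:
        ci_low, ci_high = bootstrap_ci(
            series, box_volume_a3, statistic="kd", n_boot=n_boot,
            block_len=block_len, seed=seed, estimator=estimator,
            temperature=temperature,
        )
    return ThermoEstimate(
        site=series.site, p_bound=p_b, p_unbound=p_u, kd=kd, dg=dg,
        temperature=temperature, box_volume_a3=box_volume_a3,
        ci_low=ci_low, ci_high=ci_high,
        n_binding_events=n_bind, n_unbinding_events=n_unbind,
        estimator=estimator,
    )


def thermo_table(estimates: list[ThermoEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "site": e.site,
                "P_b": e.p_bound,
                "K_d_M": e.kd,
                "CI_low_M": e.ci_low,
                "CI_high_M": e.ci_high,
                "dG_kJ_mol": e.dg,
                "n_binding": e.n_binding_events,
                "n_unbinding": e.n_unbinding_events,
                "estimator": e.estimator,
            }
        )
    return pd.DataFrame(rows)
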
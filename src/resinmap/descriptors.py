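"""Residue-level descriptor scales and occupancy-weighted aggregation.

A descriptor scale maps each of the 20 standard residues to a number
(hydropathy, hydrophilicity, aromatic affinity, charge, ...). For a protein
whose interaction surface with the resin ligand is known, each scale is
collapsed to a per-protein aggregate as the occupancy-weighted average

    d̄ = Σ_r f_r · d_r / Σ_r f_r

over the N residues of the interaction surface, where f_r is the fractional
ligand occupancy of residue r and d_r its scale value. An unnormalised
Σ f_r·d_r mode exists for sensitivity checks. The aggregates are the
predictors of the elution model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .contacts import InteractionSurface
from .io import STANDARD_RESIDUES

#: side-chain pKa values used for the charge-at-pH descriptor
DEFAULT_PKA = {
    "ASP": 3.9,
    "GLU": 4.2,
    "HIS": 6.0,
    "CYS": 8.3,
    "TYR": 10.1,
    "LYS": 10.5,
    "ARG": 12.5,
}

#: sign of the protonated side chain for titratable residues
_PROTONATED_CHARGE = {
    "ASP": 0, "GLU": 0, "CYS": 0, "TYR": 0,   # neutral acid when protonated
    "HIS": +1, "LYS": +1, "ARG": +1,            # cationic base when protonated
}
_DEPROTONATED_CHARGE = {
    "ASP": -1, "GLU": -1, "CYS": -1, "TYR": -1,
    "HIS": 0, "LYS": 0, "ARG": 0,
}


@dataclass(frozen=True)
class DescriptorScale:
    """A named residue → value map covering the 20 standard residues."""

    name: str
    values: dict[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        missing = [r for r in STANDARD_RESIDUES if r not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {missing}")
        extra = set(self.values) - set(STANDARD_RESIDUES)
        if extra:
            raise ValueError(f"scale {self.name!r} has non-standard entries {sorted(extra)}")
        for res, v in self.values.items():
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"scale {self.name!r} has non-finite value for {res}")

    def __getitem__(self, res_name: str) -> float:
        try:
            return self.values[res_name.upper()]
        except KeyError:
            raise KeyError(f"residue {res_name!r} not covered by scale {self.name!r}") from None


@dataclass
class DescriptorSet:
    """Ordered, uniquely named collection of descriptor scales."""

    scales: list[DescriptorScale] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.scales]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scale names in descriptor set")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.scales]

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)

    def add(self, scale: DescriptorScale) -> None:
        if scale.name in self.names:
            raise ValueError(f"scale {scale.name!r} already in set")
        self.scales.append(scale)


def charge_at_pH(res_name: str, pH: float, pka_table: dict[str, float] | None = None) -> int:
    """Integer side-chain charge at *pH* under the rule: protonated iff
    pH ≤ pKa (ties protonate). Non-titratable residues are 0."""
    res = res_name.upper()
    if res not in STANDARD_RESIDUES:
        raise KeyError(f"unknown residue {res_name!r}")
    pka = DEFAULT_PKA if pka_table is None else pka_table
    if res not in pka:
        return 0
    protonated = pH <= pka[res]
    return _PROTONATED_CHARGE[res] if protonated else _DEPROTONATED_CHARGE[res]


def charge_scale(pH: float = 6.0, pka_table: dict[str, float] | None = None) -> DescriptorScale:
    """Charge-at-pH as a descriptor scale (default pH 6.0, the simulation
    protonation condition)."""
    return DescriptorScale(
        name=f"charge_pH{pH:g}",
        values={r: float(charge_at_pH(r, pH, pka_table)) for r in STANDARD_RESIDUES},
    )


def arginine_indicator(res_name: str) -> int:
    """1 for arginine, 0 for any other standard residue."""
    res = res_name.upper()
    if res not in STANDARD_RESIDUES:
        raise KeyError(f"unknown residue {res_name!r}")
    return 1 if res == "ARG" else 0


def arginine_scale() -> DescriptorScale:
    """Indicator scale underlying the arginine occupancy score (AOS)."""
    return DescriptorScale(
        name="ARG_indicator",
        values={r: float(arginine_indicator(r)) for r in STANDARD_RESIDUES},
    )


def load_packaged_scale(stem: str) -> DescriptorScale:
    from .io import read_scale_csv

    ref = resources.files("resinmap") / "data" / "scales" / f"{stem}.csv"
    with resources.as_file(ref) as path:
        return read_scale_csv(path, name=stem)


_PACKAGED = {
    "AF": "aromaphilicity_synthetic",
    "HKD": "kyte_doolittle",
    "HRW": "radzicka_wolfenden",
    "HEis": "eisenberg",
    "HHW": "hopp_woods",
}


def default_descriptor_set(pH: float = 6.0) -> DescriptorSet:
    """The packaged scales: aromaphilicity (AF, synthetic stand-in),
    Kyte-Doolittle (HKD), Radzicka-Wolfenden (HRW) and Eisenberg (HEis)
    hydrophobicities, Hopp-Woods hydrophilicity (HHW), charge at pH, and the
    arginine indicator. Additional hydrophobicity scales load from user CSVs
    via :func:`resinmap.io.read_scale_csv`; the model-fitting stage accepts
    any scale set.
    """
    ds = DescriptorSet()
    for short, stem in _PACKAGED.items():
        s = load_packaged_scale(stem)
        ds.add(DescriptorScale(name=short, values=s.values))
    ds.add(charge_scale(pH=pH))
    ds.add(arginine_scale())
    return ds


def aggregate_descriptor(
    surface: InteractionSurface,
    scale: DescriptorScale,
    normalized: bool = True,
) -> float:
    """Occupancy-weighted aggregate of *scale* over *surface*.

    Default is the normalised weighted average Σ f·d / Σ f; with
    ``normalized=False`` the raw weighted sum Σ f·d is returned (sensitivity
    mode). Surface residue names must be known (surface built with a
    structure) and covered by the scale.
    """
    if surface.n_residues == 0:
        raise ValueError("cannot aggregate over an empty interaction surface")
    num = 0.0
    den = 0.0
    for res, f in surface.members.items():
        name = surface.res_names.get(res)
        if name is None or name == "":
            raise ValueError(
                f"surface residue {res} has no residue name; build the surface "
                f"with its structure"
            )
        num += f * scale[name]
        den += f
    return num / den if normalized else num


def descriptor_matrix(
    surfaces: dict[str, InteractionSurface],
    dset: DescriptorSet,
    normalized: bool = True,
) -> pd.DataFrame:
    """Protein × scale table of aggregates; rows indexed by protein id."""
    if not surfaces:
        raise ValueError("need at least one protein surface")
    rows = {}
    for protein, surf in surfaces.items():
        row = {}
        for scale in dset:
            try:
                row[scale.name] = aggregate_descriptor(surf, scale, normalized=normalized)
            except (KeyError, ValueError) as exc:
                raise type(exc)(f"protein {protein!r}, scale {scale.name!r}: {exc}") from exc
        rows[protein] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "protein"
    return df[dset.names]
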
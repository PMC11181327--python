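"""Element tables: standard atomic masses and van der Waals radii.

Masses are CODATA/IUPAC conventional atomic weights; radii are the Bondi
set commonly used for solvent-accessible-surface calculations. Both tables
cover the elements that occur in standard amino acids plus the common
hetero elements of chromatography-ligand fragments.
"""

from __future__ import annotations

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

# Bondi van der Waals radii (Å)
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


def mass_of(element: str) -> float:
    """Standard atomic mass (u) for *element* (case-insensitive symbol)."""
    try:
        return ATOMIC_MASS[element.upper()]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {element!r}") from None


def vdw_radius_of(element: str) -> float:
    """Bondi van der Waals radius (Å) for *element*."""
    try:
        return VDW_RADIUS[element.upper()]
    except KeyError:
        raise KeyError(f"no vdW radius tabulated for element {element!r}") from None
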
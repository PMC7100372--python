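"""Bundled per-element parameter table.

Covalent radii are Pyykkö-style single-bond radii (given here in angstrom,
converted to bohr on access); masses are standard atomic weights in amu.
Both are overridable per atom through the side-table / config, since force
fields and QM packages disagree on the exact radii to use for the smoothed
short-range coupling.
"""

from __future__ import annotations

from .units import AMU_TO_AU, ANGSTROM_TO_BOHR

# symbol -> (Z, covalent radius / angstrom, mass / amu)
_TABLE: dict[str, tuple[int, float, float]] = {
    "H": (1, 0.32, 1.008),
    "He": (2, 0.46, 4.0026),
    "Li": (3, 1.33, 6.94),
    "Be": (4, 1.02, 9.0122),
    "B": (5, 0.85, 10.81),
    "C": (6, 0.75, 12.011),
    "N": (7, 0.71, 14.007),
    "O": (8, 0.63, 15.999),
    "F": (9, 0.64, 18.998),
    "Ne": (10, 0.67, 20.180),
    "Na": (11, 1.55, 22.990),
    "Mg": (12, 1.39, 24.305),
    "Al": (13, 1.26, 26.982),
    "Si": (14, 1.16, 28.085),
    "P": (15, 1.11, 30.974),
    "S": (16, 1.03, 32.06),
    "Cl": (17, 0.99, 35.45),
    "Ar": (18, 0.96, 39.948),
    "K": (19, 1.96, 39.098),
    "Ca": (20, 1.71, 40.078),
    "Fe": (26, 1.16, 55.845),
    "Zn": (30, 1.18, 65.38),
    "Br": (35, 1.14, 79.904),
    "I": (53, 1.33, 126.904),
}

_BY_Z = {z: sym for sym, (z, _, _) in _TABLE.items()}


def atomic_number(symbol: str) -> int:
    return _TABLE[symbol][0]


def symbol_for(z: int) -> str:
    return _BY_Z[z]


def covalent_radius(symbol: str) -> float:
    """Covalent radius in bohr."""
    return _TABLE[symbol][1] * ANGSTROM_TO_BOHR


def mass(symbol: str) -> float:
    """Atomic mass in atomic units (electron masses)."""
    return _TABLE[symbol][2] * AMU_TO_AU


def mass_amu(symbol: str) -> float:
    return _TABLE[symbol][2]


def known_elements() -> tuple[str, ...]:
    return tuple(_TABLE)
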
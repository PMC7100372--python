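"""Coordinate and parameter-table I/O.

Coordinates come from XYZ (angstrom, native parser), GRO (nm) or PDB
(angstrom) — the latter two through MDAnalysis.  Coordinate files carry
geometry only; charges, covalent radii, LJ parameters and masses come from
a plain-text side-table with the columns

    index element charge r_c_bohr sigma_bohr epsilon_hartree mass_amu

QM subsystem definitions (Gaussian densities + core charges) travel in a
small JSON file, since no standard coordinate format carries them.
"""

from __future__ import annotations

import json

import numpy as np

from . import elements
from .coupling import MMAtom
from .errors import ConfigurationError
from .grid import GaussianSpec, QMAtom
from .units import AMU_TO_AU, ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "read_coordinates",
    "write_xyz",
    "read_side_table",
    "write_side_table",
    "build_mm_atoms",
    "read_qm_spec",
    "write_qm_spec",
]

_SIDE_COLUMNS = ("index", "element", "charge", "r_c_bohr", "sigma_bohr", "epsilon_hartree", "mass_amu")


def read_coordinates(path) -> tuple[list[str], np.ndarray]:
    """(elements, positions in bohr) from .xyz, .gro or .pdb."""
    path = str(path)
    if path.endswith(".xyz"):
        return _read_xyz(path)
    if path.endswith((".gro", ".pdb")):
        import MDAnalysis as mda

        u = mda.Universe(path)
        try:
            syms = [str(e) for e in u.atoms.elements]
        except Exception:
            syms = [str(n)[0] for n in u.atoms.names]
        # MDAnalysis normalizes coordinates to angstrom for both formats
        return syms, np.asarray(u.atoms.positions, dtype=float) * ANGSTROM_TO_BOHR
    raise ConfigurationError(f"unsupported coordinate format: {path}")


def _read_xyz(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ConfigurationError(f"{path}: bad XYZ atom count line") from None
    syms, pos = [], []
    for ln in lines[2 : 2 + n]:
        f = ln.split()
        syms.append(f[0])
        pos.append([float(x) for x in f[1:4]])
    if len(pos) != n:
        raise ConfigurationError(f"{path}: XYZ promises {n} atoms, found {len(pos)}")
    return syms, np.array(pos) * ANGSTROM_TO_BOHR


def write_xyz(path, syms, positions_bohr, comment: str = "") -> None:
    positions = np.asarray(positions_bohr, dtype=float).reshape(-1, 3) * BOHR_TO_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for sym, p in zip(syms, positions):
            fh.write(f"{sym} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def read_side_table(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            f = ln.split()
            if len(f) != len(_SIDE_COLUMNS):
                raise ConfigurationError(
                    f"{path}:{lineno}: expected {len(_SIDE_COLUMNS)} columns "
                    f"({' '.join(_SIDE_COLUMNS)}), got {len(f)}"
                )
            try:
                rows.append(
                    {
                        "index": int(f[0]),
                        "element": f[1],
                        "charge": float(f[2]),
                        "r_c": float(f[3]),
                        "sigma": float(f[4]),
                        "epsilon": float(f[5]),
                        "mass_amu": float(f[6]),
                    }
                )
            except ValueError as exc:
                raise ConfigurationError(f"{path}:{lineno}: {exc}") from None
    return rows


def write_side_table(path, mm_atoms) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_SIDE_COLUMNS) + "\n")
        for i, a in enumerate(mm_atoms):
            fh.write(
                f"{i} {a.element} {a.charge:.12g} {a.covalent_radius:.12g} "
                f"{a.lj_sigma if a.lj_sigma is not None else 0:.12g} "
                f"{a.lj_epsilon if a.lj_epsilon is not None else 0:.12g} "
                f"{a.mass / AMU_TO_AU:.12g}\n"
            )


def build_mm_atoms(positions_bohr, table: list[dict]) -> list[MMAtom]:
    positions = np.asarray(positions_bohr, dtype=float).reshape(-1, 3)
    if len(table) != len(positions):
        raise ConfigurationError(
            f"side-table has {len(table)} rows for {len(positions)} coordinates"
        )
    out = []
    for pos, row in zip(positions, table):
        r_c = row["r_c"]
        if r_c <= 0:
            if row["element"] not in elements.known_elements():
                raise ConfigurationError(
                    f"atom {row['index']}: no covalent radius and unknown element {row['element']!r}"
                )
            r_c = elements.covalent_radius(row["element"])
        out.append(
            MMAtom(
                position=pos,
                charge=row["charge"],
                covalent_radius=r_c,
                mass=row["mass_amu"] * AMU_TO_AU,
                lj_sigma=row["sigma"] or None,
                lj_epsilon=row["epsilon"] or None,
                element=row["element"],
            )
        )
    return out


def write_qm_spec(path, qm_atoms) -> None:
    data = []
    for a in qm_atoms:
        entry = {
            "position": list(a.position),
            "core_charge": a.core_charge,
            "mass_amu": a.mass / AMU_TO_AU,
            "element": a.element,
            "lj_sigma": a.lj_sigma,
            "lj_epsilon": a.lj_epsilon,
            "density": None,
        }
        if a.density_spec is not None:
            entry["density"] = {
                "width": a.density_spec.width,
                "total_charge": a.density_spec.total_charge,
            }
        data.append(entry)
    with open(path, "w") as fh:
        json.dump({"qm_atoms": data}, fh, indent=1)


def read_qm_spec(path) -> list[QMAtom]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for entry in data["qm_atoms"]:
        pos = np.array(entry["position"], dtype=float)
        spec = None
        if entry.get("density") is not None:
            spec = GaussianSpec(pos, entry["density"]["width"], entry["density"]["total_charge"])
        out.append(
            QMAtom(
                position=pos,
                core_charge=entry["core_charge"],
                mass=entry["mass_amu"] * AMU_TO_AU,
                density_spec=spec,
                lj_sigma=entry.get("lj_sigma"),
                lj_epsilon=entry.get("lj_epsilon"),
                element=entry.get("element", "X"),
            )
        )
    return out
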
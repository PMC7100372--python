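"""Gaussian cube file I/O.

The cube format stores grid *points*; this package samples densities at
voxel centers.  On write, the recorded cube origin is the first voxel
center (our cell origin shifted by half a voxel along each axis) and the
per-axis step is the voxel vector, so a write/read round trip reproduces
the grid exactly.  Both dialects are accepted on read: positive point
counts mean the vectors are in bohr, negative counts mean angstrom.
"""

from __future__ import annotations

import numpy as np

from . import elements
from .errors import CubeParseError
from .grid import DensityGrid, QMAtom
from .units import ANGSTROM_TO_BOHR

__all__ = ["read_cube", "write_cube"]


def write_cube(path, grid: DensityGrid, atoms=(), comment: str = "hembed density") -> None:
    nx, ny, nz = grid.npoints
    vv = grid.voxel_vectors
    first_center = grid.origin + 0.5 * vv.sum(axis=0)
    lines = [comment, "charge density, voxel-centered samples"]
    lines.append(_fmt_row(len(atoms), first_center))
    for a in range(3):
        lines.append(_fmt_row(grid.npoints[a], vv[a]))
    for atom in atoms:
        z = elements.atomic_number(atom.element) if atom.element in elements.known_elements() else 0
        lines.append(
            f"{z:5d}{atom.core_charge:20.12f}"
            + "".join(f"{x:20.12f}" for x in atom.position)
        )
    # wider than the classic 13.5E so that a round trip preserves values
    # to better than 1e-12 relative
    flat = grid.values.reshape(nx * ny, nz)
    for row in flat:
        for k0 in range(0, nz, 6):
            lines.append("".join(f"{v:22.13E}" for v in row[k0 : k0 + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cube(path):
    """Parse a cube file -> (DensityGrid, list[QMAtom])."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    if len(raw) < 6:
        raise CubeParseError("file too short for a cube header", line=len(raw))

    def fields(i):
        return raw[i].split()

    try:
        hdr = fields(2)
        natoms = int(hdr[0])
        first_center = np.array([float(x) for x in hdr[1:4]])
    except (ValueError, IndexError):
        raise CubeParseError("bad atom-count/origin line", line=3) from None

    npoints = []
    vectors = []
    scale = []
    for a in range(3):
        try:
            f = fields(3 + a)
            n = int(f[0])
            vec = np.array([float(x) for x in f[1:4]])
        except (ValueError, IndexError):
            raise CubeParseError("bad axis line", line=4 + a) from None
        if n == 0:
            raise CubeParseError("zero mesh points on an axis", line=4 + a)
        # negative count flags angstrom units for this axis vector
        scale.append(ANGSTROM_TO_BOHR if n < 0 else 1.0)
        npoints.append(abs(n))
        vectors.append(vec)
    vv = np.array([v * s for v, s in zip(vectors, scale)])
    if all(s != 1.0 for s in scale):
        first_center = first_center * ANGSTROM_TO_BOHR

    atoms = []
    for i in range(abs(natoms)):
        try:
            f = fields(6 + i)
            z = int(f[0])
            charge = float(f[1])
            pos = np.array([float(x) for x in f[2:5]])
        except (ValueError, IndexError):
            raise CubeParseError("bad atom record", line=7 + i) from None
        if all(s != 1.0 for s in scale):
            pos = pos * ANGSTROM_TO_BOHR
        sym = elements.symbol_for(z) if z in {elements.atomic_number(s) for s in elements.known_elements()} else "X"
        mass = elements.mass(sym) if sym != "X" else 1.0
        atoms.append(QMAtom(position=pos, core_charge=charge, mass=mass, element=sym))

    data_start = 6 + abs(natoms)
    nvals = npoints[0] * npoints[1] * npoints[2]
    values = np.empty(nvals)
    pos = 0
    for li in range(data_start, len(raw)):
        for tok in raw[li].split():
            if pos >= nvals:
                raise CubeParseError("more data values than the header promises", line=li + 1)
            try:
                values[pos] = float(tok)
            except ValueError:
                raise CubeParseError(f"bad data token {tok!r}", line=li + 1) from None
            pos += 1
    if pos != nvals:
        raise CubeParseError(
            f"short data section: got {pos} of {nvals} values", line=len(raw)
        )

    values = values.reshape(npoints)
    origin = first_center - 0.5 * vv.sum(axis=0)
    axes = vv * np.array(npoints, dtype=float)[:, None]
    return DensityGrid(origin, axes, values), atoms


def _fmt_row(n: int, vec) -> str:
    return f"{n:5d}" + "".join(f"{x:20.12f}" for x in vec)
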
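"""Real-space density grids and quadrature.

A :class:`DensityGrid` is a uniform mesh over a (generally triclinic) cell
carrying the QM charge density rho(r) in e/bohr^3.  The density is *signed*:
an electron distribution integrates to a negative total charge.  Sampling is
voxel-centered — the sample for index (i, j, k) sits at

    origin + ((i+1/2)/nx) a_x + ((j+1/2)/ny) a_y + ((k+1/2)/nz) a_z

and integrals are midpoint sums (sum of values times the voxel volume),
which is spectrally accurate for smooth, well-contained densities.

Summation discipline: every grid reduction in this package is performed as
per-X-plane partial sums (a contiguous numpy reduction per plane) combined
with an exactly rounded ``math.fsum`` over planes in index order.  The plane
is the atomic unit of reduction, so slab-decomposed evaluation reproduces
monolithic evaluation bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

__all__ = [
    "DensityGrid",
    "GaussianSpec",
    "QMAtom",
    "make_grid",
    "deposit_gaussians",
    "integrate_total_charge",
    "plane_sums",
    "reduce_planes",
]


@dataclass
class GaussianSpec:
    """An isotropic 3D Gaussian charge distribution.

    rho(r) = total_charge * (2 pi width^2)^(-3/2) * exp(-|r-center|^2 / (2 width^2))
    """

    center: np.ndarray
    width: float
    total_charge: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.width = float(self.width)
        self.total_charge = float(self.total_charge)
        if not self.width > 0:
            raise ValueError(f"Gaussian width must be positive, got {self.width}")

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Evaluate rho at an (..., 3) array of points."""
        d2 = np.sum((points - self.center) ** 2, axis=-1)
        norm = self.total_charge * (2.0 * math.pi * self.width**2) ** -1.5
        return norm * np.exp(-d2 / (2.0 * self.width**2))


@dataclass
class QMAtom:
    """A QM-subsystem atom: a point core charge plus an optional rigid
    Gaussian electron cloud that translates with it."""

    position: np.ndarray
    core_charge: float
    mass: float
    density_spec: GaussianSpec | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    element: str = "X"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not self.mass > 0:
            raise ValueError(f"QM atom mass must be positive, got {self.mass}")


@dataclass
class DensityGrid:
    origin: np.ndarray
    axes: np.ndarray  # rows are the three full-cell vectors, bohr
    values: np.ndarray  # (nx, ny, nz), e/bohr^3
    _axis_points: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidGeometryError("values must be a 3D array")
        if any(n < 2 for n in self.values.shape):
            raise InvalidGeometryError(
                f"need at least 2 mesh points per axis, got {self.values.shape}"
            )
        if abs(np.linalg.det(self.axes)) == 0.0:
            raise InvalidGeometryError("cell vectors are linearly dependent")

    # -- geometry -----------------------------------------------------------

    @property
    def npoints(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_vectors(self) -> np.ndarray:
        n = np.array(self.npoints, dtype=float)
        return self.axes / n[:, None]

    @property
    def voxel_volume(self) -> float:
        nx, ny, nz = self.npoints
        return abs(float(np.linalg.det(self.axes))) / (nx * ny * nz)

    @property
    def cell_volume(self) -> float:
        return abs(float(np.linalg.det(self.axes)))

    def axis_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center offsets Ax[i], Ay[j], Az[k], each (n, 3),
        such that center(i,j,k) = origin + Ax[i] + Ay[j] + Az[k]."""
        if self._axis_points is None:
            vv = self.voxel_vectors
            pts = []
            for a in range(3):
                idx = (np.arange(self.npoints[a], dtype=float) + 0.5)[:, None]
                pts.append(idx * vv[a][None, :])
            self._axis_points = tuple(pts)
        return self._axis_points

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape (nx, ny, nz, 3).  Allocates the full
        array; prefer :meth:`axis_points` plus broadcasting for hot paths."""
        ax, ay, az = self.axis_points()
        return (
            self.origin[None, None, None, :]
            + ax[:, None, None, :]
            + ay[None, :, None, :]
            + az[None, None, :, :]
        )

    def distances_to(self, point: np.ndarray, ix_lo: int = 0, ix_hi: int | None = None) -> np.ndarray:
        """Distances from every voxel center (optionally an X-slab
        [ix_lo, ix_hi)) to ``point``; shape (ix_hi-ix_lo, ny, nz)."""
        point = np.asarray(point, dtype=float).reshape(3)
        ax, ay, az = self.axis_points()
        if ix_hi is None:
            ix_hi = self.npoints[0]
        d2 = None
        for m in range(3):
            t = (
                self.origin[m]
                - point[m]
                + ax[ix_lo:ix_hi, m][:, None, None]
                + ay[:, m][None, :, None]
                + az[:, m][None, None, :]
            )
            d2 = t * t if d2 is None else d2 + t * t
        return np.sqrt(d2)

    def copy(self, zero: bool = False) -> "DensityGrid":
        vals = np.zeros_like(self.values) if zero else self.values.copy()
        return DensityGrid(self.origin.copy(), self.axes.copy(), vals)

    def displacement_margin(self, point: np.ndarray) -> float:
        """Smallest distance from ``point`` to any face of the cell
        (negative if outside).  Assumes an orthorhombic-ish cell; used only
        for containment warnings."""
        point = np.asarray(point, dtype=float).reshape(3)
        # fractional coordinates
        frac = np.linalg.solve(self.axes.T, point - self.origin)
        lengths = np.linalg.norm(self.axes, axis=1)
        lo = frac * lengths
        hi = (1.0 - frac) * lengths
        return float(min(lo.min(), hi.min()))


# -- reductions -------------------------------------------------------------


def plane_sums(arr: np.ndarray) -> np.ndarray:
    """Per-X-plane sums of a (nx, ny, nz) array.

    Each plane is reduced as one contiguous numpy pairwise sum, so the
    result for plane ix is independent of which slab the plane arrived in.
    """
    return arr.reshape(arr.shape[0], -1).sum(axis=1)


def reduce_planes(per_plane: np.ndarray) -> float:
    """Exactly rounded reduction of per-plane partials (index order)."""
    return math.fsum(per_plane.tolist())


# -- constructors and quadrature -------------------------------------------


def make_grid(origin, axes, npoints) -> DensityGrid:
    """Zero-filled grid over the cell spanned by ``axes`` at ``origin``."""
    npoints = tuple(int(n) for n in np.asarray(npoints).reshape(3))
    if any(n < 2 for n in npoints):
        raise InvalidGeometryError(f"need at least 2 mesh points per axis, got {npoints}")
    axes = np.asarray(axes, dtype=float).reshape(3, 3)
    if abs(np.linalg.det(axes)) == 0.0:
        raise InvalidGeometryError("cell vectors are linearly dependent")
    return DensityGrid(np.asarray(origin, dtype=float), axes, np.zeros(npoints))


def make_cubic_grid(center, edge: float, n: int) -> DensityGrid:
    """Convenience: cubic cell of the given edge centered on ``center``."""
    center = np.asarray(center, dtype=float).reshape(3)
    origin = center - 0.5 * edge
    return make_grid(origin, np.eye(3) * edge, (n, n, n))


def deposit_gaussians(grid: DensityGrid, specs) -> DensityGrid:
    """Accumulate Gaussian charge distributions onto the grid (in place).

    Warns if a Gaussian is too narrow for the mesh (width < 2 voxel edges)
    or too close to the cell boundary (< 6.5 widths), in which case the
    midpoint-quadrature guarantees of this module do not apply.
    """
    max_edge = float(np.max(np.linalg.norm(grid.voxel_vectors, axis=1)))
    ax, ay, az = grid.axis_points()
    for spec in specs:
        if spec.width < 2.0 * max_edge:
            warnings.warn(
                f"Gaussian width {spec.width:.3g} bohr < 2 voxel edges "
                f"({2*max_edge:.3g} bohr): quadrature accuracy degraded",
                stacklevel=2,
            )
        margin = grid.displacement_margin(spec.center)
        if margin < 6.5 * spec.width:
            warnings.warn(
                f"Gaussian at {spec.center} has {margin:.3g} bohr of grid "
                f"margin, less than 6.5 widths ({6.5*spec.width:.3g} bohr): "
                "tails are truncated",
                stacklevel=2,
            )
        d = grid.distances_to(spec.center)
        norm = spec.total_charge * (2.0 * math.pi * spec.width**2) ** -1.5
        grid.values += norm * np.exp(-(d * d) / (2.0 * spec.width**2))
    return grid


def integrate_total_charge(grid: DensityGrid) -> float:
    """Midpoint quadrature of the density: sum(values) * voxel volume."""
    return reduce_planes(plane_sums(grid.values)) * grid.voxel_volume
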
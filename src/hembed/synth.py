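"""Synthetic test systems.

Generates the inputs a plane-wave QM code and an MM topology would
normally provide: a gridded Gaussian "electron density" with analytically
known moments, the QM atoms carrying it, and a randomized, exactly neutral
cloud of MM point charges around it — a cartoon of a charged solute in a
polar environment.  Everything is drawn from a single seeded PRNG per
call; the stream order is positions (rejection sampling against the
exclusion sphere, three uniforms per proposal), then element indices, then
charges, so a fixed seed reproduces the system bit-for-bit.

The default MM cloud uses hydrogen-like sites.  This mirrors the regime
the hierarchical scheme is built for: the cutoff distance is much larger
than any covalent radius, so the short-range smoothing is already
indistinguishable from Coulomb where the multipole branch takes over.
"""

from __future__ import annotations

import numpy as np

from . import elements
from .coupling import MMAtom
from .grid import GaussianSpec, QMAtom, deposit_gaussians, make_cubic_grid
from .units import ANGSTROM_TO_BOHR, KCAL_MOL_TO_HARTREE

__all__ = ["make_test_system", "standard_test_system", "standard_md_system"]

# element pool for the MM cloud: LJ sigma (angstrom) and epsilon (kcal/mol)
_MM_POOL = {
    "H": (2.40, 0.030),
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (3.12, 0.210),
}


def _default_qm_spec(center: np.ndarray) -> list[GaussianSpec]:
    """A compact, asymmetric three-lobe electron density (total -6 e) so
    that dipole and higher moments are all nonzero."""
    return [
        GaussianSpec(center + np.array([0.5, 0.0, 0.0]), 1.0, -3.0),
        GaussianSpec(center + np.array([-0.4, 0.3, 0.0]), 1.0, -2.0),
        GaussianSpec(center + np.array([0.1, -0.3, 0.4]), 0.9, -1.0),
    ]


def make_test_system(
    seed: int,
    n_mm: int,
    box_edge: float = 28.0,
    qm_spec=None,
    core_charges=None,
    grid_points: int = 48,
    grid_edge: float = 16.0,
    exclusion: float = 7.0,
    min_separation: float = 5.0,
    mm_elements: tuple[str, ...] = ("H",),
):
    """Seeded synthetic system -> (DensityGrid, [QMAtom], [MMAtom]).

    The QM subsystem sits at the box center; MM atoms are uniform in the
    ``box_edge`` cube excluding a sphere of radius ``exclusion`` around the
    QM center.  MM charges are drawn uniform in [-1, 1] and mean-shifted to
    exact overall neutrality.  Covalent radii and masses come from the
    bundled element table; ``core_charges`` (one per Gaussian) default to
    the negated Gaussian charges, i.e. a neutral QM subsystem.
    """
    if n_mm < 0:
        raise ValueError(f"n_mm must be >= 0, got {n_mm}")
    rng = np.random.default_rng(seed)
    center = np.full(3, box_edge / 2.0)

    if qm_spec is None:
        qm_spec = _default_qm_spec(center)
        if core_charges is None:
            # a net -2 solute: cores under-compensate the electron cloud
            core_charges = (2.0, 1.0, 1.0)
    if core_charges is None:
        core_charges = tuple(-s.total_charge for s in qm_spec)
    if len(core_charges) != len(qm_spec):
        raise ValueError("need one core charge per Gaussian spec")

    qm_atoms = [
        QMAtom(
            position=s.center.copy(),
            core_charge=float(z),
            mass=elements.mass("C"),
            density_spec=s,
            lj_sigma=3.40 * ANGSTROM_TO_BOHR,
            lj_epsilon=0.086 * KCAL_MOL_TO_HARTREE,
            element="C",
        )
        for s, z in zip(qm_spec, core_charges)
    ]

    qm_center = np.mean([a.position for a in qm_atoms], axis=0)
    grid = make_cubic_grid(qm_center, grid_edge, grid_points)
    deposit_gaussians(grid, qm_spec)

    # rejection sampling: outside the QM exclusion sphere and at least
    # min_separation from every accepted site (a crude excluded volume,
    # preventing unphysically close charge pairs)
    positions = []
    attempts = 0
    while len(positions) < n_mm:
        attempts += 1
        if attempts > 10000 * max(n_mm, 1):
            raise ValueError(
                "could not place MM atoms: box too small for the requested "
                "count at this minimum separation"
            )
        p = rng.uniform(0.0, box_edge, size=3)
        if np.linalg.norm(p - qm_center) < exclusion:
            continue
        if positions and np.min(np.linalg.norm(np.array(positions) - p, axis=1)) < min_separation:
            continue
        positions.append(p)

    kinds = rng.integers(0, len(mm_elements), size=n_mm)
    charges = rng.uniform(-1.0, 1.0, size=n_mm)
    if n_mm:
        charges -= charges.mean()

    mm_atoms = []
    for p, k, q in zip(positions, kinds, charges):
        sym = mm_elements[k]
        lj_s, lj_e = _MM_POOL[sym]
        mm_atoms.append(
            MMAtom(
                position=p,
                charge=float(q),
                covalent_radius=elements.covalent_radius(sym),
                mass=elements.mass(sym),
                lj_sigma=lj_s * ANGSTROM_TO_BOHR,
                lj_epsilon=lj_e * KCAL_MOL_TO_HARTREE,
                element=sym,
            )
        )
    return grid, qm_atoms, mm_atoms


def standard_test_system(seed: int = 1):
    """The reference configuration used throughout the test battery:
    a three-lobe Gaussian density (total -6 e, cores +4 e, i.e. a net -2
    solute) on a 48^3 grid of edge 16 bohr, with 32 neutralized
    hydrogen-like MM charges in a 28 bohr box (7 bohr exclusion)."""
    return make_test_system(seed, n_mm=32)


def standard_md_system(seed: int = 1):
    """A lighter configuration sized for thousand-step dynamics runs:
    one Gaussian density (-2 e, width 0.8 bohr, core +2 e) on a 32^3 grid
    of edge 12.8 bohr, 16 second-row MM atoms in a 24 bohr box.

    Heavier elements and a generous excluded volume keep collision
    frequencies low enough that a 4 a.u. time step resolves every
    encounter; hydrogen-mass baths at full +-1 e charges reach impact
    speeds that would demand a smaller step."""
    center = np.full(3, 12.0)
    return make_test_system(
        seed,
        n_mm=16,
        box_edge=24.0,
        qm_spec=[GaussianSpec(center, 0.8, -2.0)],
        core_charges=(2.0,),
        grid_points=32,
        grid_edge=12.8,
        exclusion=7.0,
        min_separation=7.0,
        mm_elements=("C", "O"),
    )
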
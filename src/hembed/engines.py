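"""Surrogate engines.

Desk-scale stand-ins for the production MM and QM codes of a loosely
coupled QM/MM setup:

* the MM engine is a minimal point-charge force field — plain Coulomb,
  Lennard-Jones with Lorentz-Berthelot combination, and harmonic bonds —
  plus the LJ interactions crossing the QM/MM interface;
* the QM engine is a rigid-density surrogate: each QM atom carries a
  Gaussian charge cloud that translates with it, is re-deposited on the
  grid every evaluation, and reacts to the external potential the MM
  environment produces.  There is no self-consistency — the density does
  not polarize — which keeps every embedding formula exactly testable.
  The polarization hook exists regardless: the external potential is
  computed on the full grid each step.

All nonbonded pairs interact (no exclusions or 1-4 scaling); a bonded pair
therefore also feels Coulomb/LJ, and the harmonic term simply adds to it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coupling import center_forces_from_potential, nuclear_mm_energy_forces
from .errors import ConfigurationError, SingularityError
from .grid import DensityGrid, GaussianSpec, QMAtom

__all__ = [
    "MMTopology",
    "EngineReport",
    "mm_energy_forces",
    "interface_lj",
    "qm_engine_evaluate",
    "lorentz_berthelot",
]

_COINCIDENT = 1e-10


@dataclass
class EngineReport:
    """One tagged energy/force contribution from an engine."""

    energy: float
    forces: np.ndarray
    tag: str  # mm_internal | qm_internal | interface_lj | coupling

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if not np.all(np.isfinite(self.forces)) or not math.isfinite(self.energy):
            raise ValueError(f"non-finite engine report ({self.tag})")


@dataclass
class MMTopology:
    atoms: list
    bonds: list = field(default_factory=list)  # (i, j, r0 bohr, k hartree/bohr^2)
    lj_rule: str = "lorentz_berthelot"

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, r0, k in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ConfigurationError(f"bad bond indices ({i}, {j}) for {n} atoms")
            if k < 0:
                raise ConfigurationError(f"negative bond force constant {k}")


def lorentz_berthelot(s1, e1, s2, e2):
    return 0.5 * (s1 + s2), math.sqrt(e1 * e2)


def _lj(eps, sig, r):
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    # dE/dr
    dedr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return e, dedr


def mm_energy_forces(top: MMTopology, positions) -> EngineReport:
    """Internal MM energy and analytic forces.

    Coulomb q_i q_j / r + LJ 4 eps [(sig/r)^12 - (sig/r)^6] over all pairs
    (LJ only where both atoms carry parameters), plus harmonic bonds
    k (r - r0)^2 / 2.  Pair terms accumulate in (i, j) lexicographic order;
    energies are fsum-reduced.
    """
    positions = np.asarray(positions, dtype=float).reshape(len(top.atoms), 3)
    n = len(top.atoms)
    forces = np.zeros((n, 3))
    terms = []
    for i in range(n):
        ai = top.atoms[i]
        for j in range(i + 1, n):
            aj = top.atoms[j]
            rvec = positions[i] - positions[j]
            r = float(np.linalg.norm(rvec))
            if r < _COINCIDENT and (ai.charge or aj.charge):
                raise SingularityError(f"coincident charged MM pair ({i}, {j})")
            dedr = 0.0
            if ai.charge and aj.charge:
                e = ai.charge * aj.charge / r
                terms.append(e)
                dedr += -e / r
            if None not in (ai.lj_sigma, ai.lj_epsilon, aj.lj_sigma, aj.lj_epsilon):
                sig, eps = lorentz_berthelot(ai.lj_sigma, ai.lj_epsilon, aj.lj_sigma, aj.lj_epsilon)
                e_lj, dedr_lj = _lj(eps, sig, r)
                terms.append(e_lj)
                dedr += dedr_lj
            if dedr:
                f = -dedr * rvec / r
                forces[i] += f
                forces[j] -= f
    for i, j, r0, k in top.bonds:
        rvec = positions[i] - positions[j]
        r = float(np.linalg.norm(rvec))
        terms.append(0.5 * k * (r - r0) ** 2)
        f = -k * (r - r0) * rvec / r
        forces[i] += f
        forces[j] -= f
    return EngineReport(math.fsum(terms), forces, "mm_internal")


def interface_lj(qm, mm) -> EngineReport:
    """Lennard-Jones interactions crossing the QM/MM boundary.

    Forces are returned full-system length with the QM block first, then
    the MM block; each pair obeys Newton's third law exactly.
    """
    nq, nm = len(qm), len(mm)
    forces = np.zeros((nq + nm, 3))
    terms = []
    for a, qa in enumerate(qm):
        if qa.lj_sigma is None or qa.lj_epsilon is None:
            raise ConfigurationError(f"QM atom {a} is missing LJ parameters")
        for i, atom in enumerate(mm):
            if atom.lj_sigma is None or atom.lj_epsilon is None:
                raise ConfigurationError(f"MM atom {i} is missing LJ parameters")
            sig, eps = lorentz_berthelot(qa.lj_sigma, qa.lj_epsilon, atom.lj_sigma, atom.lj_epsilon)
            rvec = qa.position - atom.position
            r = float(np.linalg.norm(rvec))
            if r < _COINCIDENT:
                raise SingularityError(f"coincident interface pair ({a}, {i})")
            e, dedr = _lj(eps, sig, r)
            terms.append(e)
            f = -dedr * rvec / r
            forces[a] += f
            forces[nq + i] -= f
    return EngineReport(math.fsum(terms), forces, "interface_lj")


def qm_engine_evaluate(qm, external_potential, grid: DensityGrid, mm=None):
    """Rigid-density QM engine evaluation.

    Re-deposits each atom's Gaussian cloud at its current position
    (implicitly — the reaction force needs only the analytic density, not
    an updated grid), reports zero internal energy (the rigid model has no
    electronic degrees of freedom), and returns the reaction forces of the
    electronic coupling term on the density centers, computed from the
    supplied external potential.  If ``mm`` is given, the pairwise
    QM-core-MM Coulomb term is appended as a second report.

    Returns a list of :class:`EngineReport`; forces are per-QM-atom.
    """
    specs, rows = [], []
    for a, atom in enumerate(qm):
        if atom.density_spec is None:
            continue
        spec = GaussianSpec(atom.position, atom.density_spec.width, atom.density_spec.total_charge)
        margin = grid.displacement_margin(spec.center)
        if margin < 6.5 * spec.width:
            warnings.warn(
                f"QM density {a} has {margin:.3g} bohr of grid margin "
                f"(< 6.5 widths): tail truncated, forces degraded",
                stacklevel=2,
            )
        specs.append(spec)
        rows.append(a)

    forces = np.zeros((len(qm), 3))
    if specs:
        v = np.asarray(external_potential, dtype=float).reshape(grid.npoints)
        f = center_forces_from_potential(specs, v, grid)
        for row, fa in zip(rows, f):
            forces[row] += fa
    reports = [EngineReport(0.0, forces, "coupling")]
    if mm is not None:
        e_nuc, f_qm, _ = nuclear_mm_energy_forces(qm, mm)
        reports.append(EngineReport(e_nuc, f_qm, "qm_internal"))
    return reports
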
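"""Toy MM force field, interface LJ, and the rigid-density QM engine."""

import math

import numpy as np
import pytest

from hembed.coupling import MMAtom, external_potential_on_grid
from hembed.engines import (
    MMTopology,
    interface_lj,
    lorentz_berthelot,
    mm_energy_forces,
    qm_engine_evaluate,
)
from hembed.errors import ConfigurationError, SingularityError
from hembed.grid import GaussianSpec, QMAtom, deposit_gaussians, make_cubic_grid


def brute_force_mm(top, positions):
    """O(N^2) reference with independent formulas."""
    n = len(top.atoms)
    terms = []
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj = top.atoms[i], top.atoms[j]
            r = float(np.linalg.norm(positions[i] - positions[j]))
            if ai.charge and aj.charge:
                terms.append(ai.charge * aj.charge / r)
            if None not in (ai.lj_sigma, ai.lj_epsilon, aj.lj_sigma, aj.lj_epsilon):
                s = 0.5 * (ai.lj_sigma + aj.lj_sigma)
                e = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
                terms.append(4 * e * ((s / r) ** 12 - (s / r) ** 6))
    for i, j, r0, k in top.bonds:
        r = float(np.linalg.norm(positions[i] - positions[j]))
        terms.append(0.5 * k * (r - r0) ** 2)
    return math.fsum(terms)


def random_topology(seed=3, n=6, with_lj=True, with_bonds=True):
    """Jittered-lattice packing: sites stay clear of the r^-12 wall, so
    energies are O(1) and finite-difference checks are well conditioned."""
    rng = np.random.default_rng(seed)
    cells = [np.array([ix, iy, iz], dtype=float) * 6.0
             for ix in range(3) for iy in range(3) for iz in range(3)]
    atoms = []
    for k in range(n):
        atoms.append(
            MMAtom(
                cells[k] + rng.uniform(-0.8, 0.8, 3),
                rng.uniform(-0.8, 0.8),
                1.0,
                mass=1836.0,
                lj_sigma=rng.uniform(3.0, 5.0) if with_lj else None,
                lj_epsilon=rng.uniform(1e-4, 5e-4) if with_lj else None,
            )
        )
    bonds = [(0, 1, 4.0, 0.05), (2, 3, 3.0, 0.1)] if with_bonds else []
    return MMTopology(atoms, bonds)


class TestMMForceField:
    def test_coulomb_pair(self):
        top = MMTopology([
            MMAtom([0, 0, 0], 1.0, 1.0, mass=1.0),
            MMAtom([2.0, 0, 0], -1.0, 1.0, mass=1.0),
        ])
        rep = mm_energy_forces(top, [a.position for a in top.atoms])
        assert rep.energy == pytest.approx(-0.5, abs=0)
        assert rep.tag == "mm_internal"

    def test_hookes_law_bond(self):
        atoms = [
            MMAtom([0, 0, 0], 0.0, 1.0, mass=1.0),
            MMAtom([3.0, 0, 0], 0.0, 1.0, mass=1.0),
        ]
        top = MMTopology(atoms, [(0, 1, 2.0, 1.0)])
        rep = mm_energy_forces(top, [a.position for a in atoms])
        assert rep.energy == pytest.approx(0.5)
        # stretched bond pulls the atoms together
        assert rep.forces[0, 0] == pytest.approx(+1.0)
        assert rep.forces[1, 0] == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        top = random_topology()
        pos = np.array([a.position for a in top.atoms])
        rep = mm_energy_forces(top, pos)
        assert rep.energy == pytest.approx(brute_force_mm(top, pos), rel=1e-14)

    def test_forces_match_finite_difference(self):
        top = random_topology(seed=5, n=10, with_bonds=True)
        pos = np.array([a.position for a in top.atoms])
        rep = mm_energy_forces(top, pos)
        h = 1e-5
        for i in (0, 4, 9):
            for m in range(3):
                up, dn = pos.copy(), pos.copy()
                up[i, m] += h
                dn[i, m] -= h
                fd = -(mm_energy_forces(top, up).energy - mm_energy_forces(top, dn).energy) / (2 * h)
                assert rep.forces[i, m] == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_momentum_conserved_exactly(self):
        top = random_topology(seed=9, n=8)
        rep = mm_energy_forces(top, [a.position for a in top.atoms])
        assert np.max(np.abs(rep.forces.sum(axis=0))) < 1e-14

    def test_coincident_charges_raise(self):
        top = MMTopology([
            MMAtom([0, 0, 0], 1.0, 1.0, mass=1.0),
            MMAtom([0, 0, 0], -1.0, 1.0, mass=1.0),
        ])
        with pytest.raises(SingularityError):
            mm_energy_forces(top, [a.position for a in top.atoms])

    def test_bad_bond_indices(self):
        with pytest.raises(ConfigurationError):
            MMTopology([MMAtom([0, 0, 0], 0.0, 1.0, mass=1.0)], [(0, 1, 1.0, 1.0)])


class TestInterfaceLJ:
    def _pair(self, r):
        qm = [QMAtom([0, 0, 0], 0.0, 1836.0, lj_sigma=3.0, lj_epsilon=2e-4)]
        mm = [MMAtom([r, 0, 0], 0.0, 1.0, mass=1.0, lj_sigma=3.0, lj_epsilon=2e-4)]
        return qm, mm

    def test_zero_crossing_at_sigma(self):
        qm, mm = self._pair(3.0)
        rep = interface_lj(qm, mm)
        assert rep.energy == pytest.approx(0.0, abs=1e-18)

    def test_minimum_at_r_min(self):
        r_min = 2 ** (1 / 6) * 3.0
        qm, mm = self._pair(r_min)
        rep = interface_lj(qm, mm)
        assert rep.energy == pytest.approx(-2e-4, rel=1e-12)
        assert np.max(np.abs(rep.forces)) < 1e-10

    def test_newtons_third_law(self):
        qm, mm = self._pair(3.3)
        rep = interface_lj(qm, mm)
        assert np.allclose(rep.forces[0], -rep.forces[1], atol=0)

    def test_missing_parameters(self):
        qm = [QMAtom([0, 0, 0], 0.0, 1836.0)]
        mm = [MMAtom([3, 0, 0], 0.0, 1.0, mass=1.0, lj_sigma=3.0, lj_epsilon=2e-4)]
        with pytest.raises(ConfigurationError):
            interface_lj(qm, mm)

    def test_combination_rule(self):
        s, e = lorentz_berthelot(2.0, 1e-4, 4.0, 4e-4)
        assert s == 3.0
        assert e == pytest.approx(2e-4)

    def test_forces_match_finite_difference(self, md_system):
        _, qm, mm = md_system
        rep = interface_lj(qm, mm)
        h = 1e-5
        base = qm[0].position.copy()
        for m in range(3):
            up = QMAtom(base + h * np.eye(3)[m], qm[0].core_charge, qm[0].mass,
                        lj_sigma=qm[0].lj_sigma, lj_epsilon=qm[0].lj_epsilon)
            dn = QMAtom(base - h * np.eye(3)[m], qm[0].core_charge, qm[0].mass,
                        lj_sigma=qm[0].lj_sigma, lj_epsilon=qm[0].lj_epsilon)
            fd = -(interface_lj([up], mm).energy - interface_lj([dn], mm).energy) / (2 * h)
            assert rep.forces[0, m] == pytest.approx(fd, rel=1e-6, abs=1e-12)


class TestQMEngine:
    def _system(self):
        grid = make_cubic_grid([0, 0, 0], 16.0, 32)
        spec = GaussianSpec([0.5, -0.3, 0.2], 1.0, -2.0)
        deposit_gaussians(grid, [spec])
        qm = [QMAtom(spec.center, 2.0, 21894.0, density_spec=spec)]
        mm = [MMAtom([6.5, 1.0, -1.0], 0.7, 1.0, mass=1836.0)]
        return grid, qm, mm

    def test_zero_external_potential_zero_output(self):
        grid, qm, _ = self._system()
        reports = qm_engine_evaluate(qm, np.zeros(grid.npoints), grid)
        assert all(r.energy == 0.0 for r in reports)
        assert all(not np.any(r.forces) for r in reports)

    def test_translation_invariance(self):
        grid, qm, mm = self._system()
        v = external_potential_on_grid(mm, grid)
        f0 = qm_engine_evaluate(qm, v, grid)[0].forces
        shift = np.array([1.5, -2.0, 0.7])
        grid2 = make_cubic_grid(shift, 16.0, 32)
        spec2 = GaussianSpec(qm[0].position + shift, 1.0, -2.0)
        deposit_gaussians(grid2, [spec2])
        qm2 = [QMAtom(spec2.center, 2.0, 21894.0, density_spec=spec2)]
        mm2 = [MMAtom(mm[0].position + shift, 0.7, 1.0, mass=1836.0)]
        v2 = external_potential_on_grid(mm2, grid2)
        f2 = qm_engine_evaluate(qm2, v2, grid2)[0].forces
        assert np.max(np.abs(f0 - f2)) < 1e-10

    def test_out_of_margin_warns(self):
        grid, qm, mm = self._system()
        qm[0].position = np.array([6.0, 0.0, 0.0])  # 2 bohr from the face
        with pytest.warns(UserWarning, match="margin"):
            qm_engine_evaluate(qm, np.zeros(grid.npoints), grid)

    def test_reaction_force_matches_energy_finite_difference(self):
        from hembed.coupling import direct_coupling_energy

        grid, qm, mm = self._system()
        v = external_potential_on_grid(mm, grid)
        f = qm_engine_evaluate(qm, v, grid)[0].forces[0]
        h = 1e-3

        def energy_at(c):
            g = make_cubic_grid([0, 0, 0], 16.0, 32)
            deposit_gaussians(g, [GaussianSpec(c, 1.0, -2.0)])
            return direct_coupling_energy(g, mm)

        for m in range(3):
            step = h * np.eye(3)[m]
            fd = -(energy_at(qm[0].position + step) - energy_at(qm[0].position - step)) / (2 * h)
            assert f[m] == pytest.approx(fd, rel=1e-5, abs=1e-12)
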
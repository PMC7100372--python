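"""Cartesian moments, interaction derivatives, and the far-field expansion.

The sign/weight convention of the expansion is validated here against a
brute-force direct Coulomb sum over voxels — the anti-sign-error protocol:
the convention in the code is only trusted because these tests pin it.
"""

import math

import numpy as np
import pytest

from hembed.coupling import MMAtom
from hembed.errors import SingularityError
from hembed.grid import deposit_gaussians, make_cubic_grid
from oracles import brute_force_potential

from hembed.multipole import (
    compute_moments,
    farfield_energy_forces,
    farfield_potential,
    interaction_derivatives,
    multi_indices,
)


def two_voxel_dipole(a_index=2):
    """+q/-q in two voxels straddling the center along x."""
    grid = make_cubic_grid([0, 0, 0], 4.0, 8)  # 0.5 bohr voxels
    dV = grid.voxel_volume
    mid = 4  # first voxel center above 0 at x = +0.25
    grid.values[mid + a_index - 1, 4, 4] = 1.0 / dV
    grid.values[mid - a_index, 4, 4] = -1.0 / dV
    # centers sit at +-(a_index - 0.5) * 0.5 bohr in x, +0.25 offset in y,z
    a = (a_index - 0.5) * 0.5
    return grid, a


class TestMoments:
    def test_zero_grid_all_zero(self):
        g = make_cubic_grid([0, 0, 0], 4.0, 8)
        mp = compute_moments(g, [0, 0, 0], 3)
        assert all(v == 0.0 for v in mp.moments.values())

    def test_gaussian_moments_analytic(self, unit_gaussian_grid):
        mp = compute_moments(unit_gaussian_grid, [0, 0, 0], 2)
        assert mp.monopole == pytest.approx(-1.0, abs=1e-7)
        for alpha in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            assert abs(mp.moments[alpha]) < 1e-9
        # second moment of a width-sigma Gaussian: integral rho x^2 = q sigma^2
        assert mp.moments[(2, 0, 0)] == pytest.approx(-1.0, abs=1e-6)
        assert mp.moments[(0, 2, 0)] == pytest.approx(-1.0, abs=1e-6)

    def test_point_dipole_moments(self):
        grid, a = two_voxel_dipole()
        center = grid.voxel_centers()[4, 4, 4] - np.array([0.25, 0.0, 0.0])
        mp = compute_moments(grid, center, 1)
        assert mp.monopole == pytest.approx(0.0, abs=1e-14)
        assert mp.moments[(1, 0, 0)] == pytest.approx(2.0 * a, rel=1e-12)

    def test_negative_order_rejected(self):
        g = make_cubic_grid([0, 0, 0], 4.0, 8)
        with pytest.raises(ValueError):
            compute_moments(g, [0, 0, 0], -1)

    def test_monopole_translation_invariant(self, unit_gaussian_grid):
        m0 = compute_moments(unit_gaussian_grid, [0, 0, 0], 0).monopole
        m0_shift = compute_moments(unit_gaussian_grid, [2.0, -1.0, 0.5], 0).monopole
        assert m0 == pytest.approx(m0_shift, abs=1e-14)

    def test_neutral_dipole_translation_invariant(self):
        grid, a = two_voxel_dipole()
        d1 = compute_moments(grid, [0.0, 0.0, 0.0], 1).moments[(1, 0, 0)]
        d2 = compute_moments(grid, [1.3, -0.7, 0.4], 1).moments[(1, 0, 0)]
        assert d1 == pytest.approx(d2, abs=1e-10)


class TestInteractionDerivatives:
    def test_order_zero_is_coulomb(self):
        d = interaction_derivatives([2.0, 0, 0], 0)
        assert d == {(0, 0, 0): pytest.approx(0.5)}

    def test_first_derivative_closed_form(self):
        d = interaction_derivatives([2.0, 0, 0], 1)
        assert d[(1, 0, 0)] == pytest.approx(-0.25, rel=1e-14)
        assert d[(0, 1, 0)] == 0.0

    def test_against_sympy_to_order_four(self):
        sp = pytest.importorskip("sympy")
        x, y, z = sp.symbols("x y z")
        expr = 1 / sp.sqrt(x * x + y * y + z * z)
        R = np.array([0.7, -1.3, 2.1])
        derivs = interaction_derivatives(R, 4)
        subs = {x: R[0], y: R[1], z: R[2]}
        for alpha, val in derivs.items():
            ref = float(sp.diff(expr, x, alpha[0], y, alpha[1], z, alpha[2]).subs(subs))
            assert val == pytest.approx(ref, rel=1e-10, abs=1e-12)

    def test_finite_difference_cross_check(self):
        R = np.array([1.1, 0.6, -0.9])
        h = 1e-4

        def phi(p):
            return 1.0 / np.linalg.norm(p)

        derivs = interaction_derivatives(R, 2)
        for m in range(3):
            step = np.zeros(3)
            step[m] = h
            fd = (phi(R + step) - phi(R - step)) / (2 * h)
            e = tuple(1 if k == m else 0 for k in range(3))
            assert derivs[e] == pytest.approx(fd, rel=1e-7)

    def test_singularity_at_origin(self):
        with pytest.raises(SingularityError):
            interaction_derivatives([0.0, 0.0, 0.0], 2)


class TestFarfieldPotential:
    def test_monopole_is_coulomb(self):
        g = make_cubic_grid([0, 0, 0], 4.0, 8)
        g.values[4, 4, 4] = -1.0 / g.voxel_volume
        center = g.voxel_centers()[4, 4, 4]
        mp = compute_moments(g, center, 0)
        R = center + np.array([7.0, 0, 0])
        assert farfield_potential(mp, R) == pytest.approx(-1.0 / 7.0, rel=1e-12)

    def test_dipole_limit_and_sign(self):
        grid, a = two_voxel_dipole()
        center = grid.voxel_centers()[4, 4, 4] - np.array([0.25, 0.0, 0.0])
        mp = compute_moments(grid, center, 1)
        d = 40.0
        R = center + np.array([d, 0.0, 0.0])
        v = farfield_potential(mp, R)
        ref = brute_force_potential(grid, R)
        assert v == pytest.approx(2.0 * a / d**2, rel=1.5 * (a / d) ** 1)
        assert v == pytest.approx(ref, rel=1.5 * (a / d) ** 2)

    def test_convergence_rate_in_order(self):
        """Truncation error of the two-voxel dipole decays like (a/d)^(L+1)."""
        grid, a = two_voxel_dipole()
        center = grid.voxel_centers()[4, 4, 4] - np.array([0.25, 0.0, 0.0])
        R = center + np.array([6.0, 3.0, 2.0])
        ref = brute_force_potential(grid, R)
        d = np.linalg.norm(R - center)
        errs = []
        for L in range(7):
            mp = compute_moments(grid, center, L)
            errs.append(abs(farfield_potential(mp, R) - ref))
        for L in range(1, 6):
            assert errs[L + 1] <= errs[L] + 1e-15
            assert errs[L] <= 3.0 * abs(ref) * (2.0 * a / d) ** (L + 1)

    def test_spherical_gaussian_reduces_to_monopole(self, unit_gaussian_grid):
        # traced higher moments of a spherical density cancel in the
        # potential because 1/r is harmonic
        R = [30.0, 5.0, -4.0]
        d = np.linalg.norm(R)
        for L in (0, 2, 4, 6):
            mp = compute_moments(unit_gaussian_grid, [0, 0, 0], L)
            assert farfield_potential(mp, R) == pytest.approx(-1.0 / d, rel=1e-6)


class TestFarfieldEnergyForces:
    def test_empty_mm(self, unit_gaussian_grid):
        mp = compute_moments(unit_gaussian_grid, [0, 0, 0], 2)
        e, f, cf = farfield_energy_forces(mp, [])
        assert e == 0.0 and f.shape == (0, 3) and np.all(cf == 0.0)

    def test_monopole_coulomb_energy_and_force(self):
        g = make_cubic_grid([0, 0, 0], 4.0, 8)
        g.values[4, 4, 4] = -2.0 / g.voxel_volume
        center = g.voxel_centers()[4, 4, 4]
        mp = compute_moments(g, center, 0)
        d = 9.0
        mm = [MMAtom(center + [d, 0, 0], 0.5, 1.0)]
        e, f, cf = farfield_energy_forces(mp, mm)
        assert e == pytest.approx(-2.0 * 0.5 / d, rel=1e-12)
        assert f[0, 0] == pytest.approx(-2.0 * 0.5 / d**2, rel=1e-12)
        assert np.allclose(cf, -f.sum(axis=0), atol=0)

    def test_matches_brute_force_on_standard_far_atoms(self, standard_system):
        grid, qm, mm = standard_system
        center = np.mean([a.position for a in qm], axis=0)
        far = [a for a in mm if np.linalg.norm(a.position - center) >= 15.0]
        assert far, "standard system should have distant atoms"
        mp = compute_moments(grid, center, 6)
        e, _, _ = farfield_energy_forces(mp, far)
        ref = math.fsum(a.charge * brute_force_potential(grid, a.position) for a in far)
        assert e == pytest.approx(ref, rel=1e-6)

    def test_force_is_gradient_of_potential(self, unit_gaussian_grid):
        mp = compute_moments(unit_gaussian_grid, [0, 0, 0], 4)
        pos = np.array([12.0, -7.0, 3.0])
        mm = [MMAtom(pos, 0.7, 1.0)]
        _, f, _ = farfield_energy_forces(mp, mm)
        h = 1e-5
        for m in range(3):
            step = np.zeros(3)
            step[m] = h
            fd = -(0.7 * farfield_potential(mp, pos + step) - 0.7 * farfield_potential(mp, pos - step)) / (2 * h)
            assert f[0, m] == pytest.approx(fd, rel=1e-6, abs=1e-12)


def test_multi_indices_complete():
    idx = multi_indices(8)
    assert len(idx) == len(set(idx)) == 165  # C(11,3)
    assert all(sum(a) <= 8 for a in idx)
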
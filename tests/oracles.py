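"""Independent reference implementations used by the test battery.

These share no code with the production paths: kernels are evaluated as
the printed quotient, sums are explicit Python loops over voxels.
"""

import math

import numpy as np


def brute_force_energy_forces(grid, mm):
    """Triple-loop evaluation of the direct coupling energy and MM forces."""
    nx, ny, nz = grid.npoints
    vv = grid.voxel_vectors
    dV = grid.voxel_volume
    energy_terms = []
    forces = np.zeros((len(mm), 3))
    for i, atom in enumerate(mm):
        rc = atom.covalent_radius
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    r = (
                        grid.origin
                        + (ix + 0.5) * vv[0]
                        + (iy + 0.5) * vv[1]
                        + (iz + 0.5) * vv[2]
                    )
                    rho = grid.values[ix, iy, iz]
                    dvec = atom.position - r
                    d = math.sqrt(float(dvec @ dvec))
                    if abs(d - rc) < 1e-9:
                        f = 4.0 / (5.0 * rc)
                        df = -0.4 / rc**2
                    else:
                        f = (rc**4 - d**4) / (rc**5 - d**5)
                        df = (-4 * d**3 * (rc**5 - d**5) + 5 * d**4 * (rc**4 - d**4)) / (
                            rc**5 - d**5
                        ) ** 2
                    energy_terms.append(atom.charge * rho * f * dV)
                    if d > 0:
                        forces[i] -= atom.charge * rho * df * dV * dvec / d
    return math.fsum(energy_terms), forces


def brute_force_potential(grid, R):
    """Direct plain-Coulomb sum over voxels: sum rho_v dV / |R - r_v|."""
    c = grid.voxel_centers()
    d = np.linalg.norm(c - np.asarray(R, dtype=float), axis=-1)
    return float(np.sum(grid.values / d)) * grid.voxel_volume
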
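# hembed

Hierarchical electrostatic embedding for QM/MM simulations, at desk scale
and fully testable.

## The problem

In hybrid QM/MM molecular dynamics a small, chemically active region is
described by its electron density ρ<sup>QM</sup>(**r**) on a real-space
mesh, while the surrounding thousands of atoms are classical point charges
q<sub>i</sub><sup>MM</sup>. The electrostatic coupling between the two
regions is the heart of the method — it polarizes the QM density and
carries the environment's influence on the chemistry — but two numerical
hazards make the naive Coulomb coupling unusable:

1. **Electron spill-out.** A bare 1/r attraction to a nearby positive
   point charge lets grid-represented electron density leak unphysically
   onto the MM atom. The cure is a short-range-smoothed kernel, finite at
   contact:

   E<sub>QM/MM</sub> = Σ<sub>i</sub> q<sub>i</sub><sup>MM</sup> ∫ d**r** ρ<sup>QM</sup>(**r**)
   (r<sub>c,i</sub>⁴ − |**R**<sub>i</sub>−**r**|⁴) / (r<sub>c,i</sub>⁵ − |**R**<sub>i</sub>−**r**|⁵)

   where r<sub>c,i</sub> is the covalent radius of MM atom *i*. The kernel
   equals 1/r<sub>c</sub> at contact and approaches 1/d with relative error
   (r<sub>c</sub>/d)⁴ at long range. As printed, the quotient is 0/0 at
   d = r<sub>c</sub>; this package always evaluates the factored,
   singularity-free form.

2. **Cost.** The integral couples every MM atom to every mesh point.
   A hierarchical split fixes this: MM atoms within a cutoff of the QM
   subsystem are integrated directly; more distant atoms interact with an
   open-ended Cartesian multipole expansion of the density (any truncation
   order L ≥ 0), so raising L buys accuracy and permits a shorter cutoff.

`hembed` implements this coupling — energy, analytic forces on MM atoms
and on the density's centers, and the external potential on the mesh —
together with the orchestration pattern of a loosely coupled
multiple-program multiple-data (MPMD) framework: surrogate MM and QM
engines exchange coordinates and forces with the driver over a checksummed
message protocol (in-process or across OS processes, bit-identically), and
a velocity-Verlet NVE loop propagates the system. Parallel mesh/atom
decomposition is realized as a determinism contract: evaluation partitioned
over contiguous MM groups and X-slabs of the mesh reproduces the monolithic
result (bit-for-bit over slabs, ≤1e−12 relative over groups).

The QM engine is deliberately a *rigid-density* surrogate (each QM atom
carries a Gaussian cloud that translates with it, no self-consistency):
that keeps every embedding formula exactly verifiable against analytic
oracles while exercising the full data flow a real plane-wave DFT engine
would see.

## Worked example

Generate a seeded synthetic system — a net −2 e three-lobe Gaussian
"solute" density on a 48³ mesh with 32 neutralized point charges around it
— then compute the hierarchical coupling and run a short NVE trajectory:

```bash
$ hembed synth --seed 1 --out-prefix solute
wrote solute.cube/.xyz/.tbl/.qm.json (3 QM atoms, 32 MM atoms, seed 1)

$ hembed energy --density solute.cube --mm solute.xyz --params solute.tbl \
                --qm-spec solute.qm.json --cutoff 11 --order 6
near-field atoms     8
far-field atoms      24
direct (hartree)     +5.090391498017e-01
farfield (hartree)   -2.541964598610e-01
nuclear (hartree)    -1.714395235705e-01
total (hartree)      +8.340316637012e-02

$ hembed md --density solute.cube --mm solute.xyz --params solute.tbl \
            --qm-spec solute.qm.json --steps 20 --dt 4 --out-prefix demo_md
wrote demo_md.traj.xyz and demo_md.ledger.tsv (20 steps, config 7730d988218f)
max |E(t)-E(0)|/|E(0)| = 3.971e-05
```

The energy ledger splits the coupling into its three physical pieces: the
direct smoothed-kernel integral over the 8 near-field atoms, the
multipole far field over the other 24, and the plain-Coulomb interaction
of the QM core charges with all MM atoms. With an 11-bohr cutoff and
order-6 multipoles the total (+0.08340 hartree) agrees with an all-direct
evaluation to about 3×10⁻⁶ relative. The MD run conserves total energy to
a few 10⁻⁵ over its 20 steps at a 4 a.u. (≈0.1 fs) time step.

The same operations are available as a library:

```python
from hembed import (standard_test_system, EmbeddingConfig, hierarchical_coupling)

grid, qm, mm = standard_test_system(seed=1)
res = hierarchical_coupling(grid, mm, qm, EmbeddingConfig(cutoff=11.0, multipole_order=6))
print(res.energy, res.components)
```

`hembed check` runs an invariant battery (contraction identity, partition
sanity, decomposition invariance, finite-difference force check) on any
cube + coordinates + side-table input.

## Layout

| module | contents |
| --- | --- |
| `hembed.grid` | density mesh, Gaussian deposition, midpoint quadrature |
| `hembed.cube` | Gaussian cube I/O (bohr and angstrom dialects) |
| `hembed.coupling` | smoothed kernel, direct coupling energy/forces/potential |
| `hembed.multipole` | Cartesian moments, 1/r derivative recurrence, far field |
| `hembed.hierarchical` | near/far partition, assembly, decomposed evaluation |
| `hembed.engines` | toy MM force field, interface LJ, rigid-density QM engine |
| `hembed.protocol` | message frames, engine servers, both transports |
| `hembed.driver` | MPMD workflow, velocity-Verlet NVE loop, writers |
| `hembed.synth` | seeded synthetic systems |
| `hembed.cli`, `hembed.config`, `hembed.coords` | command line, config, coordinate I/O |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
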
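# Methods

## Model

The package computes the electrostatic coupling between a gridded charge
density and a set of classical point charges,

    E = sum_i q_i * integral rho(r) f(|R_i - r|, r_c,i) dr,
    f(d, r_c) = (r_c^4 - d^4) / (r_c^5 - d^5),

plus the plain-Coulomb interaction of the QM core (point) charges with
the MM charges, and assembles analytic forces for all of it. The density
is *signed*: an electron cloud carries negative total charge, the core
charges are positive, and no hidden sign flips are applied anywhere — at
long range the sum of electronic and core terms reduces to the ordinary
signed Coulomb interaction of the net QM charge.

The kernel f is the standard remedy for electron spill-out: it is finite
at contact (f(0) = 1/r_c), monotonically approaches 1/d, and deviates from
Coulomb by a relative (r_c/d)^4 at long range. The printed quotient is
0/0 at d = r_c with a removable singularity (limit 4/(5 r_c)); all
evaluation therefore goes through the factored form

    f = (r_c + d)(r_c^2 + d^2) / (r_c^4 + r_c^3 d + r_c^2 d^2 + r_c d^3 + d^4),

implemented in Horner form, and the force kernel f' is likewise derived
from the factored polynomials. f'(0) = 0, so the voxel containing an MM
atom needs no special-casing or exclusion.

### Quadrature

Densities are sampled at voxel centers and integrated by the midpoint
rule (sum times voxel volume). For a Gaussian of width sigma resolved by
at least two voxels per sigma and contained with a 6.5 sigma margin, the
midpoint rule is spectrally accurate — quadrature errors sit far below
every tolerance in the test suite (total charge of a well-resolved unit
Gaussian is reproduced to ~1e-15; the stated guarantee is 1e-7). The
deposit routine warns when either condition is violated.

### Hierarchical decomposition

MM atoms are split by a cutoff distance (default 15 bohr; the distance is
measured to the nearest QM atom by default, to a configurable expansion
center otherwise; ties go to the near, more accurate branch). Near atoms
use the direct integral. Far atoms couple to raw (traced) Cartesian
moments of the density,

    M_alpha = sum_voxels rho(r) (r - c)^alpha dV,  |alpha| <= L,

about the geometric center of the QM atoms, through the Taylor expansion
of 1/|R - r|:

    V_L(R) = sum_{|alpha| <= L} (1/alpha!) M_alpha (-1)^{|alpha|} d^alpha (1/|X|).

Raw moments rather than traceless/spherical ones: for an open-ended order
the bookkeeping is trivial, the traced parts cancel exactly in the
potential because 1/r is harmonic, and the O(L^3) moment count is
irrelevant at desk scale (L = 8 is 165 moments). Derivatives of 1/r come
from the auxiliary recurrence T^(n)_{a+e_i} = X_i T^(n+1)_a + a_i
T^(n+1)_{a-e_i} with T^(n)_0 = (-1)^n (2n-1)!!/r^(2n+1) — the
point-charge limit of the Hermite-Coulomb integral recursion — validated
against symbolic differentiation and finite differences. The sign/weight
convention was frozen only after validation against a brute-force direct
sum (the tests keep enforcing it). Default truncation order L = 4.

The QM core charges interact with *all* MM atoms pairwise, so the
near/far split concerns only the electronic term. The far-field branch
implies two approximations relative to an all-direct evaluation: the
multipole truncation, decaying like (a/d)^(L+1) where a is the density's
effective radius, and the kernel-vs-Coulomb deviation (r_c/d)^4, which no
choice of L removes. Accuracy trends in L and in the cutoff are therefore
monotone only while truncation dominates; once the truncation error falls
below the kernel-deviation floor the total error saturates and wiggles at
that floor. The trend checks in the test battery operate at cutoffs
(9-11 bohr on the reference system) where truncation still dominates.

### Forces

Forces on MM atoms are the analytic gradient of the discretized energy
(f' against the stored density). Forces on the QM side come in three
tagged parts: the reaction of the direct term on each rigid Gaussian,
computed as the *exact* gradient of the discretized energy with respect
to the center (d rho/d c is analytic for a Gaussian), so finite-difference
checks pass at quadrature precision; the reaction of the far field, which
belongs to the rigid multipole as a whole and is assigned to the QM atoms
in equal shares (exact total-momentum conservation; per-atom attribution
of a truncated approximation is not uniquely defined — energy-conserving
long NVE runs should therefore use an all-near cutoff, as the dynamics
tests do); and the pairwise core-charge forces. Newton's third law holds
pairwise for all point-charge terms and to quadrature precision
(~1e-13 relative) for the grid-mediated ones.

## Determinism and the decomposition contract

Distributed evaluation in the original setting partitions MM atoms over
task groups and the mesh over 2D slabs; at desk scale the package keeps
the *contract* and drops the parallel runtime. Every grid reduction is
performed as one contiguous numpy sum per X-plane followed by an exactly
rounded fsum over planes in index order; the plane is the atomic unit of
reduction. Consequently:

- evaluation over any slab partition is bit-identical to monolithic;
- the coupling energy is defined as the contraction of the accumulated
  external potential with rho dV, so the identity <v, rho> dV == energy
  holds bit-for-bit by construction;
- partitioning atoms into contiguous groups changes only the accumulation
  order of v, measured at <= 1e-15 relative (contract: 1e-12).

## MPMD workflow

Each step: the driver collects coordinates, sends them to the MM and QM
engines (SET_COORDS), computes the hierarchical coupling and the grid
potential itself, passes the potential to the QM engine (EVALUATE
payload), gathers tagged reports (GET_FORCES), and sums contributions in
a fixed order: mm_internal, interface_lj, coupling (MM-side + far-field +
core), QM electronic reaction. A monolithic single-call evaluation with
the same order is provided and must agree bit-for-bit (tested). The MM
and QM evaluations are independent given the step's coordinates; a test
permutes their dispatch order.

Frames are little-endian with an explicit length header and a CRC32
payload checksum; numeric payloads are raw float64, so the in-process and
two-process transports are bit-identical by construction (also tested).
Protocol-order violations and corrupted frames raise distinct error
types.

Integration is velocity Verlet, NVE only (thermostats, constraints,
other ensembles are out of scope). Default dt = 4 a.u. (~0.1 fs).

## Synthetic systems

`make_test_system` emulates a charged compact solute in a neutral polar
environment: a few Gaussian lobes (known analytic moments) deposited on a
centered cubic mesh, and MM point charges placed uniformly in a box with
two rejection rules — an exclusion sphere around the QM center (a first
solvation shell boundary) and a minimum pair separation (excluded
volume, preventing unphysically deep Coulomb contacts). Charges are drawn
uniform in [-1, 1] and mean-shifted to exact neutrality. Covalent radii,
masses and LJ parameters come from a bundled element table (Pyykkö-style
single-bond radii, standard atomic weights), overridable per atom through
the side-table.

Reference configurations, chosen once from the error model above:

- **standard system** (coupling accuracy): three Gaussian lobes totalling
  -6 e with +4 e of cores (a net -2 solute), 48^3 mesh of edge 16 bohr,
  32 hydrogen-like MM sites in a 28-bohr box, exclusion 7 bohr,
  min separation 5 bohr. Hydrogen covalent radii keep the far-field
  kernel floor (r_c/d)^4 well below the 1e-5 hierarchical-accuracy
  target at an 11-bohr cutoff — mirroring production use, where cutoffs
  (15-30 bohr) dwarf every covalent radius.
- **dynamics system**: one -2 e Gaussian (width 0.8 bohr, core +2 e) on a
  32^3 mesh, 16 C/O MM sites in a 24-bohr box, min separation 7 bohr.
  Heavier elements and the wide excluded volume keep collision
  frequencies low enough that dt = 4 a.u. resolves every encounter; a
  hydrogen-mass bath at full +-1 e charges reaches impact speeds that
  would demand a smaller step. Sizes are chosen so a 1000-step run
  completes in tens of seconds.

What these systems do *not* emulate: periodic boundaries and Ewald
electrostatics, a self-consistently polarizing density, bonded networks
(water-like molecules), exclusions/1-4 scaling, link atoms across a
covalent QM/MM boundary. Passing tests demonstrate the correctness of the
embedding algebra, force analytics, determinism contracts and integrator
— not force-field realism.

## Numerical choices

- Internal units are strictly atomic (bohr, hartree, e, a.u. mass/time);
  conversion only at I/O boundaries (angstrom for XYZ/PDB and the
  angstrom cube dialect, nm for GRO). Config files require explicit unit
  suffixes; unknown keys are rejected.
- Cube files are written with widened numeric fields (13 significant
  digits) so a write/read round trip preserves values to 1e-12 relative;
  both sign conventions of the point-count/unit flag are read.
- The energy ledger and trajectory writers are deterministic; reruns with
  identical inputs produce identical files (config hash and version are
  recorded in the header).
- Coincident point-charge pairs raise a singularity error (threshold
  1e-8 bohr for core-MM, 1e-10 for MM-MM); the grid-mediated terms need
  no such guard.
- NVE quality on the dynamics system: max |E(t)-E(0)|/|E(0)| = 4.6e-5
  over 1000 steps at dt = 4 a.u., scaling as dt^2 (ratio 4.001 against
  dt = 2 over the same physical time); time reversal after 100 steps
  returns to the start within 1e-15 bohr; per-step momentum drift
  ~3e-14 a.u. (These numbers are recomputed by the test battery and
  scripts/acceptance.py, not asserted from this file.)

## Known limitations

- The rigid-density QM engine cannot show polarization effects; the
  external potential is computed and exported each step precisely so a
  self-consistent engine could be dropped in behind the same protocol.
- Per-atom attribution of the far-field reaction force is an equal-share
  convention (see Forces above); hierarchical far fields during MD
  trade a small NVE violation for speed, exactly as the approximation
  intends, and the conservation tests use all-direct coupling.
- No periodic images: all electrostatics are open-boundary.
- The smoothed kernel is applied to the electronic term only; whether the
  core-charge term should share it is exposed as the `nuclear_kernel`
  config switch (default plain Coulomb — spill-out is a property of the
  density, not of point cores).
- The default covalent-radius table is an implementation choice; any
  production use against a specific QM/MM code should override radii per
  atom via the side-table to match that code's convention.
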
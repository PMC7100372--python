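"""MPMD-style orchestration and NVE dynamics.

One MD step follows the collect -> dispatch -> evaluate -> sum -> propagate
workflow of a loosely coupled QM/MM framework: the driver collects the
current coordinates, dispatches them to the MM and QM engines (over an
in-process or a two-process transport), computes the electrostatic
coupling terms itself, sums all tagged force contributions in a fixed
documented order, and advances the state with velocity Verlet (NVE only).

Fixed force-summation order: mm_internal, interface_lj, coupling (MM-side
direct + far field + core reaction + pairwise nuclear), qm electronic
reaction.  A monolithic single-call evaluation with the same order is
provided for the workflow-equivalence contract.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .engines import MMTopology, interface_lj, mm_energy_forces
from .errors import EngineError
from .grid import DensityGrid, GaussianSpec
from .hierarchical import EmbeddingConfig, hierarchical_coupling
from .protocol import EngineClient, make_transport, mm_engine_spec, qm_engine_spec
from .units import BOHR_TO_ANGSTROM

__all__ = ["SystemState", "MDContext", "Trajectory", "run_md_step", "run_md", "evaluate_monolithic"]


@dataclass
class SystemState:
    """Full dynamical state; QM atoms occupy the leading rows."""

    positions: np.ndarray  # (N, 3) bohr
    velocities: np.ndarray  # (N, 3) bohr / a.u. time
    masses: np.ndarray  # (N,) a.u.
    labels: list  # "QM" | "MM" per atom
    dt: float  # a.u. time
    step: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        n = len(self.positions)
        if not (len(self.velocities) == len(self.masses) == len(self.labels) == n):
            raise ValueError("state arrays have inconsistent lengths")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_qm(self) -> int:
        return sum(1 for l in self.labels if l == "QM")

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))

    def momentum(self) -> np.ndarray:
        return np.sum(self.masses[:, None] * self.velocities, axis=0)


def state_from_system(qm, mm, dt: float = 4.0) -> SystemState:
    """Initial state (velocities zero) from QM/MM atom lists."""
    atoms = list(qm) + list(mm)
    return SystemState(
        positions=np.array([a.position for a in atoms]),
        velocities=np.zeros((len(atoms), 3)),
        masses=np.array([a.mass for a in atoms]),
        labels=["QM"] * len(qm) + ["MM"] * len(mm),
        dt=dt,
    )


class MDContext:
    """Engines plus the static problem definition for an MD run."""

    def __init__(self, grid_template: DensityGrid, qm, mm, cfg: EmbeddingConfig,
                 bonds=(), transport: str = "in_process"):
        import copy

        self.grid_template = grid_template.copy(zero=True)
        # private copies: force evaluation syncs atom positions to the MD
        # state and must not mutate the caller's objects
        self.qm = [copy.deepcopy(a) for a in qm]
        self.mm = [copy.deepcopy(a) for a in mm]
        self.cfg = cfg
        self.topology = MMTopology(self.mm, list(bonds))
        self.transport = transport
        self.mm_client = EngineClient(make_transport(transport))
        self.mm_client.init(mm_engine_spec(self.topology, self.qm))
        self.qm_client = EngineClient(make_transport(transport))
        self.qm_client.init(qm_engine_spec(self.qm, self.grid_template))

    def close(self):
        self.mm_client.finalize()
        self.qm_client.finalize()

    # -- one full force evaluation ------------------------------------------

    def _sync(self, state: SystemState):
        n_qm = len(self.qm)
        for a, atom in enumerate(self.qm):
            atom.position = state.positions[a].copy()
            if atom.density_spec is not None:
                atom.density_spec = GaussianSpec(
                    atom.position, atom.density_spec.width, atom.density_spec.total_charge
                )
        for i, atom in enumerate(self.mm):
            atom.position = state.positions[n_qm + i].copy()

    def deposit_density(self) -> DensityGrid:
        grid = self.grid_template.copy(zero=True)
        specs = [a.density_spec for a in self.qm if a.density_spec is not None]
        norm_sum = np.zeros(grid.npoints)
        for s in specs:
            d = grid.distances_to(s.center)
            norm_sum += s.total_charge * (2.0 * math.pi * s.width**2) ** -1.5 * np.exp(
                -(d * d) / (2.0 * s.width**2)
            )
        grid.values += norm_sum
        return grid

    def evaluate(self, state: SystemState):
        """Collect coordinates, dispatch to engines, compute coupling, sum
        forces in fixed order.  Returns (forces (N,3), ledger dict)."""
        self._sync(state)
        n_qm, n = len(self.qm), len(state.positions)
        try:
            self.mm_client.set_coords(state.positions, state.step)
            self.qm_client.set_coords(state.positions, state.step)
        except Exception as exc:
            raise EngineError("coordinate dispatch failed", step=state.step) from exc

        grid = self.deposit_density()
        coupling = hierarchical_coupling(grid, self.mm, self.qm, self.cfg,
                                         include_center_reaction=False)

        try:
            self.mm_client.evaluate(None, state.step)
            self.qm_client.evaluate(coupling.grid_potential, state.step)
            mm_reports = self.mm_client.get_forces(state.step)
            qm_reports = self.qm_client.get_forces(state.step)
        except Exception as exc:
            raise EngineError("engine evaluation failed", step=state.step) from exc

        by_tag = {r.tag: r for r in mm_reports}
        by_tag.update({r.tag: r for r in qm_reports})

        forces = np.zeros((n, 3))
        forces += by_tag["mm_internal"].forces
        if "interface_lj" in by_tag:
            forces += by_tag["interface_lj"].forces
        coupling_full = np.zeros((n, 3))
        coupling_full[:n_qm] = coupling.qm_forces
        coupling_full[n_qm:] = coupling.mm_forces
        forces += coupling_full
        reaction = by_tag["coupling"].forces
        forces[:n_qm] += reaction[:n_qm]

        ledger = {
            "mm_internal": by_tag["mm_internal"].energy,
            "interface_lj": by_tag["interface_lj"].energy if "interface_lj" in by_tag else 0.0,
            "qm_internal": by_tag.get("qm_internal").energy if "qm_internal" in by_tag else 0.0,
            "coupling_direct": coupling.components["direct"],
            "coupling_farfield": coupling.components["farfield"],
            "coupling_nuclear": coupling.components["nuclear"],
        }
        ledger["potential"] = math.fsum(ledger.values())
        return forces, ledger


def evaluate_monolithic(state: SystemState, ctx: MDContext):
    """Single-call evaluation of every term through direct library calls,
    bypassing the engine protocol, with the same fixed summation order as
    :meth:`MDContext.evaluate`.  The workflow-equivalence contract requires
    bit-identical forces between the two paths."""
    ctx._sync(state)
    n_qm, n = len(ctx.qm), len(state.positions)
    grid = ctx.deposit_density()
    coupling = hierarchical_coupling(grid, ctx.mm, ctx.qm, ctx.cfg,
                                     include_center_reaction=False)
    internal = mm_energy_forces(ctx.topology, [a.position for a in ctx.mm])
    forces = np.zeros((n, 3))
    forces[n_qm:] += internal.forces
    if n_qm:
        iface = interface_lj(ctx.qm, ctx.mm)
        forces += iface.forces
    coupling_full = np.zeros((n, 3))
    coupling_full[:n_qm] = coupling.qm_forces
    coupling_full[n_qm:] = coupling.mm_forces
    forces += coupling_full
    from .coupling import center_forces_from_potential

    specs = [a.density_spec for a in ctx.qm if a.density_spec is not None]
    if specs:
        rows = [a for a, atom in enumerate(ctx.qm) if atom.density_spec is not None]
        reaction = center_forces_from_potential(specs, coupling.grid_potential, grid)
        for row, f in zip(rows, reaction):
            forces[row] += f
    terms = [internal.energy, iface.energy if n_qm else 0.0, 0.0,
             coupling.components["direct"], coupling.components["farfield"],
             coupling.components["nuclear"]]
    return forces, math.fsum(terms)


# -- integration -------------------------------------------------------------


@dataclass
class Trajectory:
    states: list = field(default_factory=list)
    ledgers: list = field(default_factory=list)

    @property
    def final(self) -> SystemState:
        return self.states[-1]

    def total_energies(self) -> np.ndarray:
        return np.array([l["total"] for l in self.ledgers])


def run_md_step(state: SystemState, ctx: MDContext, forces: np.ndarray | None = None):
    """One velocity-Verlet step; returns (new_state, new_forces, ledger)."""
    if forces is None:
        forces, _ = ctx.evaluate(state)
    acc = forces / state.masses[:, None]
    v_half = state.velocities + 0.5 * state.dt * acc
    new_pos = state.positions + state.dt * v_half
    new_state = replace(
        state,
        positions=new_pos,
        velocities=v_half,
        masses=state.masses.copy(),
        labels=list(state.labels),
        step=state.step + 1,
    )
    new_forces, ledger = ctx.evaluate(new_state)
    new_state.velocities = v_half + 0.5 * state.dt * new_forces / state.masses[:, None]
    ledger = dict(ledger)
    ledger["kinetic"] = new_state.kinetic_energy()
    ledger["total"] = ledger["potential"] + ledger["kinetic"]
    return new_state, new_forces, ledger


def run_md(initial: SystemState, n_steps: int, ctx: MDContext, writers=None) -> Trajectory:
    """NVE trajectory of ``n_steps`` velocity-Verlet steps.

    ``writers`` is an optional (xyz_writer, ledger_writer) pair; one frame
    and one ledger row are emitted for the initial state and after every
    step."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    traj = Trajectory()
    forces, ledger = ctx.evaluate(initial)
    ledger = dict(ledger)
    ledger["kinetic"] = initial.kinetic_energy()
    ledger["total"] = ledger["potential"] + ledger["kinetic"]
    state = initial
    traj.states.append(state)
    traj.ledgers.append(ledger)
    _emit(writers, state, ledger)
    for _ in range(n_steps):
        state, forces, ledger = run_md_step(state, ctx, forces)
        traj.states.append(state)
        traj.ledgers.append(ledger)
        _emit(writers, state, ledger)
    return traj


def _emit(writers, state, ledger):
    if writers is None:
        return
    xyz_writer, ledger_writer = writers
    if xyz_writer is not None:
        xyz_writer.write_frame(state)
    if ledger_writer is not None:
        ledger_writer.write_row(state.step, ledger)


LEDGER_COLUMNS = [
    "step", "kinetic", "mm_internal", "interface_lj", "qm_internal",
    "coupling_direct", "coupling_farfield", "coupling_nuclear", "potential", "total",
]


class XYZTrajectoryWriter:
    """Appends frames in XYZ format (angstrom)."""

    def __init__(self, path, elements):
        self.fh = open(path, "w")
        self.elements = list(elements)

    def write_frame(self, state: SystemState):
        self.fh.write(f"{len(state.positions)}\n")
        self.fh.write(f"step {state.step}\n")
        for sym, pos in zip(self.elements, state.positions):
            x, y, z = pos * BOHR_TO_ANGSTROM
            self.fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")
        self.fh.flush()

    def close(self):
        self.fh.close()


class EnergyLedgerWriter:
    """Tab-separated per-step energy ledger (hartree)."""

    def __init__(self, path, header_comment: str = ""):
        self.fh = open(path, "w")
        if header_comment:
            self.fh.write(f"# {header_comment}\n")
        self.fh.write("\t".join(LEDGER_COLUMNS) + "\n")

    def write_row(self, step: int, ledger: dict):
        row = [str(step)] + [f"{ledger[c]:.12e}" for c in LEDGER_COLUMNS[1:]]
        self.fh.write("\t".join(row) + "\n")
        self.fh.flush()

    def close(self):
        self.fh.close()


def config_hash(cfg: EmbeddingConfig, dt: float, n_steps: int, seed) -> str:
    blob = repr((cfg, dt, n_steps, seed)).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
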
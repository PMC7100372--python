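"""Engine wire protocol and transports.

The orchestrator talks to each engine through a small command protocol
modeled on a loosely coupled multiple-program, multiple-data (MPMD)
framework: the same engine code can run inside the driver process or as a
separate OS process connected by pipes, and the physics is bit-identical
either way because the numeric payloads are raw little-endian float64 and
the computation is the same code path.

Frame layout (little endian):

    magic   4 bytes  b"HMB1"
    command 1 byte
    step    4 bytes  uint32
    length  8 bytes  uint64, payload byte count
    payload length bytes
    crc32   4 bytes  of the payload

Commands must arrive in protocol order INIT -> (SET_COORDS -> EVALUATE ->
GET_ENERGY/GET_FORCES)* -> FINALIZE; violations raise
:class:`~hembed.errors.ProtocolError`, checksum or framing damage raises
:class:`~hembed.errors.TransportError`.
"""

from __future__ import annotations

import json
import struct
import subprocess
import sys
import zlib
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .coupling import MMAtom
from .engines import EngineReport, MMTopology, interface_lj, mm_energy_forces, qm_engine_evaluate
from .errors import ProtocolError, TransportError
from .grid import DensityGrid, GaussianSpec, QMAtom

__all__ = [
    "Command",
    "Message",
    "EngineServer",
    "EngineClient",
    "InProcessTransport",
    "TwoProcessTransport",
    "engine_roundtrip",
]

MAGIC = b"HMB1"
_HEADER = struct.Struct("<4sBIQ")
_CRC = struct.Struct("<I")


class Command(IntEnum):
    INIT = 1
    SET_COORDS = 2
    EVALUATE = 3
    GET_ENERGY = 4
    GET_FORCES = 5
    FINALIZE = 6
    REPLY = 16
    ERROR = 17


@dataclass
class Message:
    command: Command
    payload: bytes = b""
    step: int = 0

    def encode(self) -> bytes:
        head = _HEADER.pack(MAGIC, int(self.command), self.step, len(self.payload))
        return head + self.payload + _CRC.pack(zlib.crc32(self.payload))

    @classmethod
    def decode(cls, raw: bytes) -> "Message":
        if len(raw) < _HEADER.size + _CRC.size:
            raise TransportError("short frame")
        magic, cmd, step, length = _HEADER.unpack_from(raw)
        if magic != MAGIC:
            raise TransportError(f"bad magic {magic!r}")
        if len(raw) != _HEADER.size + length + _CRC.size:
            raise TransportError("frame length mismatch")
        payload = raw[_HEADER.size : _HEADER.size + length]
        (crc,) = _CRC.unpack_from(raw, _HEADER.size + length)
        if crc != zlib.crc32(payload):
            raise TransportError("payload checksum mismatch")
        return cls(Command(cmd), payload, step)


# -- engine construction specs ----------------------------------------------


def _mm_atom_to_dict(a: MMAtom) -> dict:
    return {
        "position": list(a.position),
        "charge": a.charge,
        "covalent_radius": a.covalent_radius,
        "mass": a.mass,
        "lj_sigma": a.lj_sigma,
        "lj_epsilon": a.lj_epsilon,
        "element": a.element,
    }


def _qm_atom_to_dict(a: QMAtom) -> dict:
    d = {
        "position": list(a.position),
        "core_charge": a.core_charge,
        "mass": a.mass,
        "lj_sigma": a.lj_sigma,
        "lj_epsilon": a.lj_epsilon,
        "element": a.element,
        "density_spec": None,
    }
    if a.density_spec is not None:
        s = a.density_spec
        d["density_spec"] = {
            "center": list(s.center),
            "width": s.width,
            "total_charge": s.total_charge,
        }
    return d


def mm_engine_spec(topology: MMTopology, qm_atoms) -> dict:
    """INIT payload for the MM engine: the full topology plus the QM atoms
    it needs for the interface LJ terms."""
    return {
        "engine": "mm",
        "atoms": [_mm_atom_to_dict(a) for a in topology.atoms],
        "bonds": [list(b) for b in topology.bonds],
        "qm_atoms": [_qm_atom_to_dict(a) for a in qm_atoms],
    }


def qm_engine_spec(qm_atoms, grid: DensityGrid) -> dict:
    """INIT payload for the QM engine: the QM atoms and the grid geometry
    on which the external potential will arrive."""
    return {
        "engine": "qm",
        "qm_atoms": [_qm_atom_to_dict(a) for a in qm_atoms],
        "grid": {
            "origin": list(grid.origin),
            "axes": [list(r) for r in grid.axes],
            "npoints": list(grid.npoints),
        },
    }


def _mm_atom_from_dict(d: dict) -> MMAtom:
    return MMAtom(
        position=np.array(d["position"]),
        charge=d["charge"],
        covalent_radius=d["covalent_radius"],
        mass=d["mass"],
        lj_sigma=d["lj_sigma"],
        lj_epsilon=d["lj_epsilon"],
        element=d["element"],
    )


def _qm_atom_from_dict(d: dict) -> QMAtom:
    spec = None
    if d["density_spec"] is not None:
        s = d["density_spec"]
        spec = GaussianSpec(np.array(s["center"]), s["width"], s["total_charge"])
    return QMAtom(
        position=np.array(d["position"]),
        core_charge=d["core_charge"],
        mass=d["mass"],
        density_spec=spec,
        lj_sigma=d["lj_sigma"],
        lj_epsilon=d["lj_epsilon"],
        element=d["element"],
    )


# -- server side -------------------------------------------------------------

_TAG_IDS = {"mm_internal": 1, "interface_lj": 2, "qm_internal": 3, "coupling": 4}
_TAG_NAMES = {v: k for k, v in _TAG_IDS.items()}


class _MMEngineCore:
    def __init__(self, spec: dict):
        atoms = [_mm_atom_from_dict(d) for d in spec["atoms"]]
        self.topology = MMTopology(atoms, [tuple(b) for b in spec["bonds"]])
        self.qm_atoms = [_qm_atom_from_dict(d) for d in spec["qm_atoms"]]
        self.n_qm = len(self.qm_atoms)
        self.n_total = self.n_qm + len(atoms)

    def set_coords(self, coords: np.ndarray):
        coords = coords.reshape(self.n_total, 3)
        for a, atom in enumerate(self.qm_atoms):
            atom.position = coords[a].copy()
        for i, atom in enumerate(self.topology.atoms):
            atom.position = coords[self.n_qm + i].copy()

    def evaluate(self, aux: np.ndarray | None):
        internal = mm_energy_forces(self.topology, [a.position for a in self.topology.atoms])
        full = np.zeros((self.n_total, 3))
        full[self.n_qm :] = internal.forces
        reports = [EngineReport(internal.energy, full, "mm_internal")]
        if self.n_qm:
            reports.append(interface_lj(self.qm_atoms, self.topology.atoms))
        return reports


class _QMEngineCore:
    def __init__(self, spec: dict):
        self.qm_atoms = [_qm_atom_from_dict(d) for d in spec["qm_atoms"]]
        g = spec["grid"]
        self.grid = DensityGrid(
            np.array(g["origin"]), np.array(g["axes"]), np.zeros(tuple(g["npoints"]))
        )
        self.n_qm = len(self.qm_atoms)

    def set_coords(self, coords: np.ndarray):
        coords = coords.reshape(-1, 3)
        for a, atom in enumerate(self.qm_atoms):
            atom.position = coords[a].copy()

    def evaluate(self, aux: np.ndarray | None):
        if aux is None:
            aux = np.zeros(self.grid.npoints)
        reports = qm_engine_evaluate(self.qm_atoms, aux, self.grid)
        out = []
        for r in reports:
            full = np.zeros((max(len(r.forces), self.n_qm), 3))
            full[: len(r.forces)] = r.forces
            out.append(EngineReport(r.energy, full, r.tag))
        # the rigid model has no internal QM energy; report it explicitly
        out.append(EngineReport(0.0, np.zeros_like(out[0].forces), "qm_internal"))
        return out


_CORES = {"mm": _MMEngineCore, "qm": _QMEngineCore}


class EngineServer:
    """Protocol state machine around one engine core."""

    def __init__(self):
        self.core = None
        self.have_coords = False
        self.reports: list[EngineReport] | None = None
        self.finalized = False

    def handle(self, msg: Message) -> Message:
        try:
            return self._dispatch(msg)
        except ProtocolError as exc:
            return Message(Command.ERROR, json.dumps({"kind": "protocol", "message": str(exc)}).encode(), msg.step)
        except Exception as exc:  # engine failure propagates with context
            return Message(Command.ERROR, json.dumps({"kind": "engine", "message": str(exc)}).encode(), msg.step)

    def handle_frame(self, raw: bytes) -> bytes:
        try:
            msg = Message.decode(raw)
        except TransportError as exc:
            return Message(Command.ERROR, json.dumps({"kind": "transport", "message": str(exc)}).encode()).encode()
        return self.handle(msg).encode()

    def _dispatch(self, msg: Message) -> Message:
        cmd = msg.command
        if self.finalized:
            raise ProtocolError(f"{cmd.name} after FINALIZE")
        if cmd == Command.INIT:
            if self.core is not None:
                raise ProtocolError("duplicate INIT")
            spec = json.loads(msg.payload.decode())
            self.core = _CORES[spec["engine"]](spec)
            return Message(Command.REPLY, b"", msg.step)
        if self.core is None:
            raise ProtocolError(f"{cmd.name} before INIT")
        if cmd == Command.SET_COORDS:
            coords = np.frombuffer(msg.payload, dtype="<f8")
            self.core.set_coords(coords.astype(float))
            self.have_coords = True
            self.reports = None
            return Message(Command.REPLY, b"", msg.step)
        if cmd == Command.EVALUATE:
            if not self.have_coords:
                raise ProtocolError("EVALUATE before SET_COORDS")
            aux = np.frombuffer(msg.payload, dtype="<f8").astype(float) if msg.payload else None
            self.reports = self.core.evaluate(aux)
            return Message(Command.REPLY, b"", msg.step)
        if cmd in (Command.GET_ENERGY, Command.GET_FORCES):
            if self.reports is None:
                raise ProtocolError(f"{cmd.name} before EVALUATE")
            return Message(Command.REPLY, _encode_reports(self.reports, cmd == Command.GET_FORCES), msg.step)
        if cmd == Command.FINALIZE:
            self.finalized = True
            return Message(Command.REPLY, b"", msg.step)
        raise ProtocolError(f"unknown command {cmd}")


def _encode_reports(reports, with_forces: bool) -> bytes:
    out = [struct.pack("<I", len(reports))]
    for r in reports:
        out.append(struct.pack("<Bd", _TAG_IDS[r.tag], r.energy))
        if with_forces:
            flat = np.ascontiguousarray(r.forces, dtype="<f8")
            out.append(struct.pack("<Q", flat.shape[0]))
            out.append(flat.tobytes())
        else:
            out.append(struct.pack("<Q", 0))
    return b"".join(out)


def _decode_reports(payload: bytes) -> list[EngineReport]:
    (count,) = struct.unpack_from("<I", payload)
    off = 4
    reports = []
    for _ in range(count):
        tag_id, energy = struct.unpack_from("<Bd", payload, off)
        off += struct.calcsize("<Bd")
        (n,) = struct.unpack_from("<Q", payload, off)
        off += 8
        forces = np.frombuffer(payload, dtype="<f8", count=3 * n, offset=off).reshape(n, 3).copy()
        off += 24 * n
        reports.append(EngineReport(energy, forces, _TAG_NAMES[tag_id]))
    return reports


# -- client side -------------------------------------------------------------


class InProcessTransport:
    """Runs the engine server in the driver process, but through the same
    encode/decode path as the two-process transport."""

    def __init__(self):
        self.server = EngineServer()

    def roundtrip(self, frame: bytes) -> bytes:
        return self.server.handle_frame(frame)

    def close(self):
        pass


class TwoProcessTransport:
    """Runs the engine server as a separate OS process over pipes."""

    def __init__(self):
        self.proc = subprocess.Popen(
            [sys.executable, "-m", "hembed.engine_server"],
            stdin=subprocess.PIPE,
            stdout=subprocess.PIPE,
        )

    def roundtrip(self, frame: bytes) -> bytes:
        self.proc.stdin.write(struct.pack("<Q", len(frame)) + frame)
        self.proc.stdin.flush()
        raw = self.proc.stdout.read(8)
        if len(raw) != 8:
            raise TransportError("engine process closed the pipe")
        (n,) = struct.unpack("<Q", raw)
        reply = self.proc.stdout.read(n)
        if len(reply) != n:
            raise TransportError("truncated reply from engine process")
        return reply

    def close(self):
        if self.proc.poll() is None:
            self.proc.stdin.close()
            self.proc.wait(timeout=10)


def make_transport(kind: str):
    if kind == "in_process":
        return InProcessTransport()
    if kind == "two_process":
        return TwoProcessTransport()
    raise ValueError(f"unknown transport {kind!r}")


class EngineClient:
    """Typed wrapper over a transport; raises on ERROR replies."""

    def __init__(self, transport):
        self.transport = transport

    def _call(self, command: Command, payload: bytes = b"", step: int = 0) -> Message:
        reply = Message.decode(self.transport.roundtrip(Message(command, payload, step).encode()))
        if reply.command == Command.ERROR:
            info = json.loads(reply.payload.decode())
            kind = info.get("kind")
            if kind == "protocol":
                raise ProtocolError(info["message"])
            if kind == "transport":
                raise TransportError(info["message"])
            raise RuntimeError(info.get("message", "engine error"))
        return reply

    def init(self, spec: dict):
        self._call(Command.INIT, json.dumps(spec).encode())

    def set_coords(self, coords: np.ndarray, step: int = 0):
        flat = np.ascontiguousarray(coords, dtype="<f8")
        self._call(Command.SET_COORDS, flat.tobytes(), step)

    def evaluate(self, aux: np.ndarray | None = None, step: int = 0):
        payload = b"" if aux is None else np.ascontiguousarray(aux, dtype="<f8").tobytes()
        self._call(Command.EVALUATE, payload, step)

    def get_energy(self, step: int = 0) -> list[EngineReport]:
        return _decode_reports(self._call(Command.GET_ENERGY, step=step).payload)

    def get_forces(self, step: int = 0) -> list[EngineReport]:
        return _decode_reports(self._call(Command.GET_FORCES, step=step).payload)

    def finalize(self):
        self._call(Command.FINALIZE)
        self.transport.close()


def engine_roundtrip(spec: dict, coords: np.ndarray, transport: str, aux: np.ndarray | None = None):
    """INIT -> SET_COORDS -> EVALUATE -> GET_FORCES -> FINALIZE over the
    chosen transport ('in_process' or 'two_process'); returns the reports."""
    client = EngineClient(make_transport(transport))
    client.init(spec)
    client.set_coords(coords)
    client.evaluate(aux)
    reports = client.get_forces()
    client.finalize()
    return reports
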
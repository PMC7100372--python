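"""Plain-text configuration with explicit units.

Config files are ``key = value`` lines (``#`` comments).  Every physical
value must carry a unit suffix — ``cutoff = 15 bohr`` or
``cutoff = 7.9 angstrom`` — because silent unit guessing is the main user
hazard in a field that mixes bohr, angstrom and nm.  Unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ConfigurationError
from .hierarchical import EmbeddingConfig
from .units import ANGSTROM_TO_BOHR, KCAL_MOL_TO_HARTREE, NM_TO_BOHR

__all__ = ["RunConfig", "parse_config_file", "parse_quantity"]

_LENGTH = {"bohr": 1.0, "angstrom": ANGSTROM_TO_BOHR, "nm": NM_TO_BOHR}
_ENERGY = {"hartree": 1.0, "kcal_mol": KCAL_MOL_TO_HARTREE}
_TIME = {"au": 1.0}


def parse_quantity(text: str, kind: str) -> float:
    """Parse '15 bohr' / '7.9 angstrom' / '0.5 hartree' -> atomic units."""
    scales = {"length": _LENGTH, "energy": _ENERGY, "time": _TIME}[kind]
    parts = text.split()
    if len(parts) != 2:
        raise ConfigurationError(
            f"{text!r}: expected '<number> <unit>' with unit in {sorted(scales)}"
        )
    try:
        value = float(parts[0])
    except ValueError:
        raise ConfigurationError(f"{text!r}: bad number {parts[0]!r}") from None
    if parts[1] not in scales:
        raise ConfigurationError(f"{text!r}: unknown unit {parts[1]!r}, expected one of {sorted(scales)}")
    return value * scales[parts[1]]


@dataclass
class RunConfig:
    """Resolved run parameters, all in atomic units."""

    cutoff: float = 15.0
    multipole_order: int = 4
    distance_rule: str = "nearest_qm_atom"
    nuclear_kernel: str = "coulomb"
    n_groups: int = 1
    n_slabs: int = 1
    dt: float = 4.0
    n_steps: int = 0
    seed: int = 1
    transport: str = "in_process"
    output_prefix: str = "run"
    density: str | None = None
    coordinates: str | None = None
    params: str | None = None
    qm_spec: str | None = None

    def embedding(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            cutoff=self.cutoff,
            multipole_order=self.multipole_order,
            distance_rule=self.distance_rule,
            nuclear_kernel=self.nuclear_kernel,
            n_groups=self.n_groups,
            n_slabs=self.n_slabs,
        )


_QUANTITY_KEYS = {"cutoff": "length", "dt": "time"}
_INT_KEYS = {"multipole_order", "n_groups", "n_slabs", "n_steps", "seed"}
_STR_KEYS = {
    "distance_rule", "nuclear_kernel", "transport", "output_prefix",
    "density", "coordinates", "params", "qm_spec",
}


def parse_config_file(path) -> RunConfig:
    known = {f.name for f in fields(RunConfig)}
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                if key in _QUANTITY_KEYS:
                    values[key] = parse_quantity(val, _QUANTITY_KEYS[key])
                elif key in _INT_KEYS:
                    values[key] = int(val)
                else:
                    values[key] = val
            except ConfigurationError as exc:
                raise ConfigurationError(f"{path}:{lineno}: {exc}") from None
            except ValueError:
                raise ConfigurationError(f"{path}:{lineno}: bad value {val!r} for {key!r}") from None
    return RunConfig(**values)
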
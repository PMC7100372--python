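"""Exception hierarchy."""


class HembedError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(HembedError, ValueError):
    """Degenerate cell vectors or an unusable mesh."""


class CubeParseError(HembedError, ValueError):
    """Malformed Gaussian cube file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SingularityError(HembedError, ZeroDivisionError):
    """Evaluation requested at a point where the kernel/potential diverges."""


class ConfigurationError(HembedError, ValueError):
    """Missing or inconsistent parameters (side-table, config file, CLI)."""


class ProtocolError(HembedError, RuntimeError):
    """Engine message received out of protocol order."""


class TransportError(HembedError, RuntimeError):
    """Corrupted or truncated engine message frame."""


class EngineError(HembedError, RuntimeError):
    """An engine failed during evaluation; carries step index and tag."""

    def __init__(self, message: str, step: int | None = None, tag: str | None = None):
        self.step = step
        self.tag = tag
        parts = [message]
        if step is not None:
            parts.append(f"step={step}")
        if tag is not None:
            parts.append(f"engine={tag}")
        super().__init__("; ".join(parts))
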
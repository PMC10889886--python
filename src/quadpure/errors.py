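"""Exception hierarchy shared across the control stack.

Every error raised by quadpure derives from :class:`QuadpureError`; the
client middleware maps server-side error codes back onto these types so a
scripted run fails with the same exception whether the engine is driven
directly or over the wire.
"""

from __future__ import annotations


class QuadpureError(Exception):
    """Base class for all quadpure errors."""

    #: short machine-readable code carried in wire messages
    code = "error"


class ValidationError(QuadpureError):
    """A config, protocol, or command argument failed validation."""

    code = "validation"


class RoutingError(QuadpureError):
    """Requested (source, sink) pair is not reachable in the fluidic graph."""

    code = "routing"


class BusError(QuadpureError):
    """I2C bus address collision, capacity overflow, or unknown address."""

    code = "bus"


class DeviceStateError(QuadpureError):
    """A peripheral command was issued in an illegal device state."""

    code = "device-state"


class ConfigurationError(QuadpureError):
    """Unknown configuration name, or config loaded/absent when it must not be."""

    code = "configuration"


class SharedBufferConflictError(QuadpureError):
    """A rotary-port change was requested while another channel is flowing
    from a different buffer port (single shared rotary valve + splitter)."""

    code = "shared-buffer-conflict"


class PumpCommandError(QuadpureError):
    """Pump command outside the flow envelope, zero volume, or pump busy."""

    code = "pump-command"


class CompileError(QuadpureError):
    """A protocol cannot be compiled against the active rig configuration."""

    code = "compile"


class RunStateError(QuadpureError):
    """Illegal run-state transition (e.g. resume from IDLE)."""

    code = "run-state"


class CalibrationError(QuadpureError):
    """Flow calibration failed (e.g. measured volume is zero)."""

    code = "calibration"


class ProtocolFileError(ValidationError):
    """A protocol or config file failed to parse or validate."""

    code = "protocol-file"


class ServerBusyError(QuadpureError):
    """Connection refused: another client holds the server lock."""

    code = "busy"


class ServerError(QuadpureError):
    """An ERROR reply from the server, carrying its code and detail."""

    def __init__(self, code: str, detail: str):
        super().__init__(f"[{code}] {detail}")
        self.code = code
        self.detail = detail


#: wire code -> exception class, used by the client to re-raise typed errors
CODE_MAP = {
    cls.code: cls
    for cls in (
        ValidationError,
        RoutingError,
        BusError,
        DeviceStateError,
        ConfigurationError,
        SharedBufferConflictError,
        PumpCommandError,
        CompileError,
        RunStateError,
        CalibrationError,
        ProtocolFileError,
        ServerBusyError,
    )
}
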
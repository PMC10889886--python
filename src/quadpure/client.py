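"""Client-side middleware and high-level command wrappers.

A :class:`ClientSession` speaks the newline-JSON command protocol: it
assigns strictly increasing request ids, validates that every reply stream
is ACK-then-terminal with matching ids, surfaces server ERROR replies as the
typed exceptions the server raised, and exposes the purification vocabulary
(equilibrate / load / wash / elute / purge / calibrate and run control) as
one-call wrappers so an operator's script reads like the bench protocol it
automates.  :func:`discover` listens for the server's idle UDP broadcasts;
:func:`run_protocol_file` runs a protocol file end-to-end against a local
simulated server and writes the ledger CSV and run summary.
"""

from __future__ import annotations

import json
import logging
import socket
import time
from pathlib import Path
from typing import Callable, Dict, List, Optional, Union

from .control import ConfigRegistry
from .errors import (
    CODE_MAP,
    ConfigurationError,
    ServerBusyError,
    ServerError,
    ValidationError,
)
from .protocol import (
    Protocol,
    ProtocolStep,
    RunLedger,
    StepKind,
    load_protocol,
)
from .server import DEFAULT_STATUS_PORT, LineChannel, Message, PurifierServer

logger = logging.getLogger("quadpure.client")

#: status payloads observed while awaiting a terminal may trigger control
#: commands: the callback returns command names to send ("pause", ...)
StatusCallback = Callable[[dict], Optional[List[str]]]


def discover(status_port: int = DEFAULT_STATUS_PORT,
             window_s: float = 1.5) -> list[dict]:
    """Listen for availability broadcasts; return one entry per server heard.

    Busy servers do not broadcast, so an instrument under another client's
    control is simply absent from the result.  Returns an empty list if
    nothing is heard within the window.
    """
    sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
    sock.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
    sock.bind(("", status_port))
    sock.settimeout(0.2)
    seen: dict[str, dict] = {}
    deadline = time.monotonic() + window_s
    try:
        while time.monotonic() < deadline:
            try:
                data, _ = sock.recvfrom(65536)
            except socket.timeout:
                continue
            try:
                msg = Message.model_validate(json.loads(data))
            except Exception:
                continue
            if msg.msg_type == "STATUS" and msg.payload:
                seen[msg.payload.get("server", "?")] = msg.payload
    finally:
        sock.close()
    return list(seen.values())


class ClientSession:
    """One client's hold on the instrument's command channel."""

    def __init__(self, host: str, port: int, timeout_s: float = 60.0) -> None:
        self.address = (host, port)
        sock = socket.create_connection(self.address, timeout=timeout_s)
        sock.settimeout(None)
        self.chan = LineChannel(sock, log=logger)
        self.selected_config: Optional[str] = None
        self._next_id = 1
        self.connected = False
        greeting = self._read_message(timeout=timeout_s)
        if greeting.msg_type == "ERROR":
            err = greeting.error or {}
            self.chan.close()
            raise ServerBusyError(
                f"server busy (held by {err.get('holder', 'unknown')})")
        self.connected = True
        logger.info("connected to %s:%d", host, port)

    # -- plumbing -----------------------------------------------------------

    def _read_message(self, timeout: Optional[float] = None) -> Message:
        line = self.chan.recv_line(timeout)
        if not line:
            raise ServerError("connection", "server closed the connection")
        return Message.model_validate(json.loads(line))

    def request(self, command: str, on_status: Optional[StatusCallback] = None,
                **args) -> dict:
        """Issue one command; return the COMPLETE payload or raise the error."""
        if not self.connected:
            raise ServerError("connection", "session is closed")
        rid = self._next_id
        self._next_id += 1
        self.chan.send(Message(msg_type="REQUEST", request_id=rid,
                               command=command, args=args).model_dump())
        self._await_ack(rid)
        return self._await_terminal(rid, on_status)

    def _await_ack(self, rid: int) -> None:
        while True:
            msg = self._read_message()
            if msg.msg_type == "STATUS":
                continue
            if msg.msg_type == "ACK":
                if msg.request_id != rid:
                    raise ValidationError(
                        f"ACK for request {msg.request_id}, expected {rid}")
                return
            if msg.msg_type == "ERROR" and msg.request_id is None:
                err = msg.error or {}
                raise ServerError(err.get("code", "error"),
                                  err.get("detail", ""))
            raise ValidationError(f"expected ACK, got {msg.msg_type}")

    def _await_terminal(self, rid: int,
                        on_status: Optional[StatusCallback]) -> dict:
        pending: list[int] = []
        while True:
            msg = self._read_message()
            if msg.msg_type == "STATUS":
                if on_status is not None and msg.payload is not None:
                    for cmd in (on_status(msg.payload) or []):
                        nid = self._next_id
                        self._next_id += 1
                        pending.append(nid)
                        self.chan.send(Message(
                            msg_type="REQUEST", request_id=nid,
                            command=cmd).model_dump())
                continue
            if msg.msg_type == "ACK":
                if msg.request_id not in pending:
                    raise ValidationError(
                        f"unexpected ACK for request {msg.request_id}")
                continue
            if msg.msg_type in ("COMPLETE", "ERROR"):
                if msg.request_id in pending:
                    pending.remove(msg.request_id)
                    if msg.msg_type == "ERROR":
                        err = msg.error or {}
                        logger.warning("nested control failed: %s", err)
                    continue
                if msg.request_id != rid:
                    raise ValidationError(
                        f"terminal for request {msg.request_id}, "
                        f"expected {rid}")
                if msg.msg_type == "ERROR":
                    err = msg.error or {}
                    code = err.get("code", "error")
                    exc_cls = CODE_MAP.get(code)
                    detail = err.get("detail", "")
                    if exc_cls is not None:
                        raise exc_cls(detail)
                    raise ServerError(code, detail)
                return msg.payload or {}

    # -- connection management ---------------------------------------------

    def disconnect(self) -> None:
        """Release the server lock.  Best-effort: a connection that already
        died (e.g. a forced disconnect mid-run) is simply closed."""
        if not self.connected:
            return
        self.connected = False
        try:
            if not self.chan.closed:
                rid = self._next_id
                self._next_id += 1
                self.chan.send(Message(msg_type="REQUEST", request_id=rid,
                                       command="disconnect").model_dump())
                # drain any stale replies until our terminal or EOF
                for _ in range(100):
                    line = self.chan.recv_line(timeout=1.0)
                    if not line:
                        break
                    msg = Message.model_validate(json.loads(line))
                    if msg.msg_type in ("COMPLETE", "ERROR") \
                            and msg.request_id == rid:
                        break
        except (OSError, ValueError, ServerError):
            pass
        finally:
            self.chan.close()

    def __enter__(self) -> "ClientSession":
        return self

    def __exit__(self, *exc) -> None:
        self.disconnect()

    # -- configuration ------------------------------------------------------

    def list_configs(self) -> list[str]:
        return self.request("list_configs")["configs"]

    def select_config(self, name: str) -> dict:
        payload = self.request("select_config", name=name)
        self.selected_config = name
        return payload

    def reset_config(self) -> None:
        self.request("reset_config")
        self.selected_config = None

    def status(self) -> dict:
        return self.request("status")

    def _require_config(self) -> None:
        # client-side guard: no REQUEST is sent for a doomed wrapper call
        if self.selected_config is None:
            raise ConfigurationError(
                "select_config must be called before issuing commands")

    # -- step wrappers ------------------------------------------------------

    def _run_step(self, step: ProtocolStep,
                  channels: Optional[List[int]] = None,
                  overrides: Optional[Dict[int, float]] = None,
                  on_status: Optional[StatusCallback] = None) -> RunLedger:
        self._require_config()
        payload = self.request(
            "run_step", step=step.model_dump(mode="json"),
            channels=channels,
            overrides={str(k): v for k, v in (overrides or {}).items()} or None,
            on_status=on_status)
        return RunLedger.from_dict(payload["ledger"])

    def equilibrate(self, buffer_port: int, volume_cv: float,
                    rate_cv_per_min: float = 1.0, **kw) -> RunLedger:
        return self._run_step(ProtocolStep(
            kind=StepKind.EQUILIBRATE, buffer_port=buffer_port,
            volume_cv=volume_cv, rate_cv_per_min=rate_cv_per_min), **kw)

    def load(self, volume_cv: float, collect_flowthrough: bool = False,
             rate_cv_per_min: float = 1.0, **kw) -> RunLedger:
        return self._run_step(ProtocolStep(
            kind=StepKind.LOAD, volume_cv=volume_cv,
            collect_flowthrough=collect_flowthrough,
            rate_cv_per_min=rate_cv_per_min), **kw)

    def wash(self, buffer_port: int, volume_cv: float,
             rate_cv_per_min: float = 1.0, **kw) -> RunLedger:
        return self._run_step(ProtocolStep(
            kind=StepKind.WASH, buffer_port=buffer_port,
            volume_cv=volume_cv, rate_cv_per_min=rate_cv_per_min), **kw)

    def elute(self, buffer_port: int, volume_cv: float,
              fraction_size_cv: float, prefill_cv: float = 0.0,
              rate_cv_per_min: float = 1.0, **kw) -> RunLedger:
        return self._run_step(ProtocolStep(
            kind=StepKind.ELUTE, buffer_port=buffer_port,
            volume_cv=volume_cv, fraction_size_cv=fraction_size_cv,
            prefill_cv=prefill_cv, rate_cv_per_min=rate_cv_per_min), **kw)

    def purge(self, buffer_port: int, volume_cv: float,
              rate_cv_per_min: float = 1.0, **kw) -> RunLedger:
        return self._run_step(ProtocolStep(
            kind=StepKind.PURGE, buffer_port=buffer_port,
            volume_cv=volume_cv, rate_cv_per_min=rate_cv_per_min), **kw)

    def calibrate(self, channels: Optional[List[int]] = None,
                  target_rate_cv_per_min: float = 1.0,
                  window_min: float = 1.0) -> Dict[int, float]:
        self._require_config()
        payload = self.request("calibrate", channels=channels,
                               target_rate_cv_per_min=target_rate_cv_per_min,
                               window_min=window_min)
        return {int(k): v for k, v in payload["volume_per_step_ul"].items()}

    def set_flow_path(self, channel: int, source: dict, sink: str) -> dict:
        self._require_config()
        return self.request("set_flow_path", channel=channel, source=source,
                            sink=sink)

    def stop_all(self) -> None:
        self._require_config()
        self.request("stop_all")

    def ledger(self) -> RunLedger:
        self._require_config()
        return RunLedger.from_dict(self.request("ledger")["ledger"])

    # -- protocol runs ------------------------------------------------------

    def run_protocol(self, protocol: Union[Protocol, str],
                     channels: Optional[List[int]] = None,
                     overrides: Optional[Dict[int, float]] = None,
                     on_status: Optional[StatusCallback] = None) -> RunLedger:
        """Run a full protocol (a :class:`Protocol` or a shipped name)."""
        self._require_config()
        args: dict = {
            "channels": channels,
            "overrides": {str(k): v
                          for k, v in (overrides or {}).items()} or None,
        }
        if isinstance(protocol, str):
            args["protocol_name"] = protocol
        else:
            args["protocol"] = protocol.model_dump(mode="json")
        payload = self.request("run_protocol", on_status=on_status, **args)
        self.last_run_state = payload["run_state"]
        return RunLedger.from_dict(payload["ledger"])


def connect(host: str, port: int, **kw) -> ClientSession:
    """Connect to a purifier server; raises ServerBusyError if refused."""
    return ClientSession(host, port, **kw)


def parse_channels(spec: Optional[str]) -> Optional[List[int]]:
    """Parse a channel selector like ``"1-4"``, ``"2"`` or ``"1,3"``."""
    if spec is None:
        return None
    channels: list[int] = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-", 1)
            channels.extend(range(int(lo), int(hi) + 1))
        elif part:
            channels.append(int(part))
    if not channels:
        raise ValidationError(f"empty channel selector {spec!r}")
    return channels


def run_protocol_file(path: Union[str, Path, Protocol],
                      config_name: Optional[str] = None,
                      channels: Optional[List[int]] = None,
                      overrides: Optional[Dict[int, float]] = None,
                      report_dir: Optional[Path] = None,
                      address: Optional[tuple[str, int]] = None,
                      registry: Optional[ConfigRegistry] = None,
                      seed: int = 0,
                      on_status: Optional[StatusCallback] = None) -> RunLedger:
    """Run a protocol file end-to-end; optionally write report files.

    With no ``address`` a local simulated server is started for the run.
    ``config_name`` defaults to the protocol's own name (the shipped
    protocols pair with configs of the same name).  Writes ``ledger.csv``
    and ``summary.txt`` into ``report_dir`` when given.
    """
    if isinstance(path, Protocol):
        protocol = path
    else:
        protocol = load_protocol(Path(path))
    config_name = config_name or protocol.name

    def _run(session: ClientSession) -> RunLedger:
        session.select_config(config_name)
        return session.run_protocol(protocol, channels=channels,
                                    overrides=overrides, on_status=on_status)

    if address is not None:
        with ClientSession(*address) as session:
            ledger = _run(session)
    else:
        with PurifierServer(registry=registry, status_port=0,
                            broadcast_interval_s=30.0, seed=seed) as server:
            with ClientSession(server.host, server.command_port) as session:
                ledger = _run(session)

    if report_dir is not None:
        report_dir = Path(report_dir)
        report_dir.mkdir(parents=True, exist_ok=True)
        ledger.to_dataframe().to_csv(report_dir / "ledger.csv", index=False)
        (report_dir / "summary.txt").write_text(ledger.summary() + "\n")
    return ledger
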
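"""Always-on control service: UDP availability broadcast, single-client TCP
command channel, and dual acknowledgement.

Wire format: newline-delimited JSON records over TCP for commands and
replies; JSON datagrams over UDP for idle-status broadcasts.  Every REQUEST
is answered by exactly one ACK (receipt) followed by exactly one terminal
COMPLETE or ERROR (outcome), matching the client-assigned ``request_id``.
Long-running commands (protocol execution) additionally stream STATUS
progress records between their ACK and terminal, and accept nested
run-control requests (pause / resume / hold / abort / status) on the same
connection while they execute.

Only one client may hold the command channel at a time; further connection
attempts are refused with a busy ERROR naming the holder.  While no client
is connected the server broadcasts a STATUS datagram each interval; the
broadcast stops while the lock is held and resumes on disconnect.  A client
must select a hardware configuration before any hardware command is
accepted; disconnecting (or a forced disconnect) aborts any run, resets the
controller to a safe state, and frees the lock.
"""

from __future__ import annotations

import json
import logging
import select
import socket
import threading
import time
from typing import Literal, Optional

import pydantic

from .control import ConfigRegistry, HardwareController
from .errors import (
    ConfigurationError,
    QuadpureError,
    RunStateError,
    ValidationError,
)
from .fluidics import FlowSink, FlowSource, SourceKind
from .protocol import (
    Protocol,
    ProtocolEngine,
    ProtocolStep,
    RunState,
    get_protocol,
)

logger = logging.getLogger("quadpure.server")

DEFAULT_COMMAND_PORT = 47310
DEFAULT_STATUS_PORT = 47311
DEFAULT_BROADCAST_INTERVAL_S = 1.0

#: commands accepted before a configuration has been selected
_PRE_CONFIG_COMMANDS = {"select_config", "list_configs", "status", "disconnect"}
#: run-control commands serviced while a protocol is executing
_RUN_CONTROL_COMMANDS = {"pause", "resume", "hold", "abort", "status"}


class Message(pydantic.BaseModel):
    """One wire record (either direction)."""

    msg_type: Literal["REQUEST", "ACK", "COMPLETE", "ERROR", "STATUS"]
    request_id: Optional[int] = None
    command: Optional[str] = None
    args: dict = pydantic.Field(default_factory=dict)
    payload: Optional[dict] = None
    error: Optional[dict] = None

    model_config = pydantic.ConfigDict(extra="forbid")


class LineChannel:
    """Newline-delimited JSON over one TCP socket, with timeout reads."""

    def __init__(self, sock: socket.socket, log: logging.Logger = logger) -> None:
        self.sock = sock
        self.log = log
        self._buf = b""
        self.closed = False

    def send(self, record: dict) -> None:
        data = json.dumps(record, separators=(",", ":")).encode() + b"\n"
        self.log.debug("send %s", data.decode().rstrip())
        try:
            self.sock.sendall(data)
        except OSError:
            self.closed = True
            raise

    def recv_line(self, timeout: Optional[float]) -> Optional[str]:
        """Return one line, ``None`` on EOF, or ``""`` on timeout."""
        if self.closed:
            return None
        deadline = None if timeout is None else time.monotonic() + timeout
        while b"\n" not in self._buf:
            if deadline is None:
                wait = None
            else:
                wait = max(0.0, deadline - time.monotonic())
            r, _, _ = select.select([self.sock], [], [], wait)
            if not r:
                return ""
            try:
                chunk = self.sock.recv(65536)
            except OSError:
                self.closed = True
                return None
            if not chunk:
                self.closed = True
                return None
            self._buf += chunk
        line, self._buf = self._buf.split(b"\n", 1)
        text = line.decode()
        self.log.debug("recv %s", text)
        return text

    def close(self) -> None:
        self.closed = True
        try:
            self.sock.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self.sock.close()


def _source_from_wire(d: dict) -> FlowSource:
    kind = d.get("kind")
    if kind == "buffer":
        return FlowSource.buffer(d["buffer_port"])
    if kind == "load":
        return FlowSource.load(d["channel"])
    raise ValidationError(f"unknown source kind {kind!r}")


class ClientGone(Exception):
    """The command connection vanished (disconnect or forced)."""


class PurifierServer:
    """The instrument-side service, running over the simulated rig."""

    def __init__(self,
                 registry: Optional[ConfigRegistry] = None,
                 host: str = "127.0.0.1",
                 command_port: int = 0,
                 status_port: int = DEFAULT_STATUS_PORT,
                 broadcast_addr: str = "127.0.0.1",
                 broadcast_interval_s: float = DEFAULT_BROADCAST_INTERVAL_S,
                 name: str = "quadpure-sim",
                 seed: int = 0) -> None:
        self.registry = registry or ConfigRegistry()
        self.host = host
        self.command_port = command_port      # actual port known after start()
        self.status_port = status_port
        self.broadcast_addr = broadcast_addr
        self.broadcast_interval_s = broadcast_interval_s
        self.name = name
        self.seed = seed

        self.controller = HardwareController(self.registry)
        self.controller.set_seed(seed)
        self.engine: Optional[ProtocolEngine] = None

        self._listener: Optional[socket.socket] = None
        self._stop = threading.Event()
        self._session_mutex = threading.Lock()
        self._active_client: Optional[str] = None
        self._active_chan: Optional[LineChannel] = None
        self._threads: list[threading.Thread] = []
        self.broadcast_count = 0

    # -- lifecycle ----------------------------------------------------------

    def start(self) -> "PurifierServer":
        self._listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._listener.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._listener.bind((self.host, self.command_port))
        self._listener.listen(16)
        self._listener.settimeout(0.2)   # lets the accept loop notice stop()
        self.command_port = self._listener.getsockname()[1]
        logger.info("server %s listening on %s:%d", self.name, self.host,
                    self.command_port)
        for target in (self._accept_loop, self._broadcast_loop):
            t = threading.Thread(target=target, daemon=True)
            t.start()
            self._threads.append(t)
        return self

    def stop(self) -> None:
        self._stop.set()
        self.force_disconnect()
        if self._listener is not None:
            try:
                self._listener.close()
            except OSError:
                pass
        for t in self._threads:
            t.join(timeout=5.0)

    def __enter__(self) -> "PurifierServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    @property
    def client_connected(self) -> bool:
        return self._active_client is not None

    def force_disconnect(self) -> None:
        """Sever the active client: abort any run, free the lock."""
        with self._session_mutex:
            chan = self._active_chan
        if chan is not None:
            logger.info("forcing disconnect of %s", self._active_client)
            chan.close()    # session thread unwinds and resets the rig

    # -- broadcast ----------------------------------------------------------

    def _status_payload(self) -> dict:
        run = self.engine.run if self.engine else None
        return {
            "server": self.name,
            "host": self.host,
            "command_port": self.command_port,
            "busy": self.client_connected,
            "config": self.controller.state.active_config,
            "run_state": run.state.value if run else RunState.IDLE.value,
        }

    def _broadcast_loop(self) -> None:
        sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        sock.setsockopt(socket.SOL_SOCKET, socket.SO_BROADCAST, 1)
        try:
            while not self._stop.is_set():
                # status_port 0/None disables broadcasting (embedded servers)
                if self.status_port and not self.client_connected:
                    record = Message(msg_type="STATUS",
                                     payload=self._status_payload()).model_dump()
                    data = json.dumps(record).encode()
                    try:
                        sock.sendto(data, (self.broadcast_addr, self.status_port))
                        self.broadcast_count += 1
                        logger.debug("broadcast %s", data.decode())
                    except OSError as exc:
                        logger.warning("broadcast failed: %s", exc)
                self._stop.wait(self.broadcast_interval_s)
        finally:
            sock.close()

    # -- sessions -----------------------------------------------------------

    def _accept_loop(self) -> None:
        while not self._stop.is_set():
            try:
                conn, addr = self._listener.accept()
            except socket.timeout:
                continue
            except OSError:
                return
            conn.settimeout(None)
            chan = LineChannel(conn)
            ident = f"{addr[0]}:{addr[1]}"
            with self._session_mutex:
                if self._active_client is not None:
                    logger.info("refusing %s: lock held by %s", ident,
                                self._active_client)
                    try:
                        chan.send(Message(
                            msg_type="ERROR",
                            error={"code": "busy",
                                   "detail": "another client holds the lock",
                                   "holder": self._active_client}).model_dump())
                    except OSError:
                        pass
                    chan.close()
                    continue
                self._active_client = ident
                self._active_chan = chan
            t = threading.Thread(target=self._session, args=(chan, ident),
                                 daemon=True)
            t.start()
            self._threads.append(t)

    def _session(self, chan: LineChannel, ident: str) -> None:
        logger.info("client %s connected", ident)
        self.engine = ProtocolEngine(self.controller)
        try:
            chan.send(Message(msg_type="STATUS",
                              payload=self._status_payload()).model_dump())
            while not self._stop.is_set():
                line = chan.recv_line(timeout=0.5)
                if line is None:
                    break
                if line == "":
                    continue
                try:
                    self._handle_request(chan, line, nested=False)
                except ClientGone:
                    break
        finally:
            chan.close()
            # reset the rig to a safe state and free the lock
            try:
                self.controller.reset()
            except QuadpureError:
                pass
            self.engine = None
            with self._session_mutex:
                self._active_client = None
                self._active_chan = None
            logger.info("client %s disconnected; rig reset", ident)

    # -- dispatch -----------------------------------------------------------

    def _handle_request(self, chan: LineChannel, line: str,
                        nested: bool) -> None:
        try:
            raw = json.loads(line)
            msg = Message.model_validate(raw)
            if msg.msg_type != "REQUEST" or msg.request_id is None \
                    or not msg.command:
                raise ValueError("not a REQUEST with id and command")
        except (json.JSONDecodeError, pydantic.ValidationError, ValueError) as exc:
            self._send(chan, Message(msg_type="ERROR",
                                     error={"code": "parse",
                                            "detail": str(exc)}))
            return

        self._send(chan, Message(msg_type="ACK", request_id=msg.request_id,
                                 command=msg.command))
        if msg.command == "disconnect":
            self._send(chan, Message(msg_type="COMPLETE",
                                     request_id=msg.request_id,
                                     payload={"bye": True}))
            raise ClientGone
        try:
            if nested:
                payload = self._dispatch_nested(chan, msg)
            else:
                payload = self._dispatch(chan, msg)
        except QuadpureError as exc:
            self._send(chan, Message(
                msg_type="ERROR", request_id=msg.request_id,
                error={"code": getattr(exc, "code", "error"),
                       "detail": str(exc)}))
            return
        except (KeyError, TypeError, ValueError) as exc:
            self._send(chan, Message(
                msg_type="ERROR", request_id=msg.request_id,
                error={"code": "validation", "detail": repr(exc)}))
            return
        self._send(chan, Message(msg_type="COMPLETE", request_id=msg.request_id,
                                 payload=payload))

    def _send(self, chan: LineChannel, msg: Message) -> None:
        try:
            chan.send(msg.model_dump())
        except OSError:
            raise ClientGone from None

    def _dispatch_nested(self, chan: LineChannel, msg: Message) -> dict:
        run = self.engine.run
        cmd = msg.command
        if cmd == "status":
            return self._run_status()
        if cmd not in _RUN_CONTROL_COMMANDS:
            raise RunStateError(
                f"command {cmd!r} not available while a run is in progress")
        getattr(run, cmd)()   # pause / resume / hold / abort
        return self._run_status()

    def _run_status(self) -> dict:
        run = self.engine.run
        return {"run_state": run.state.value, "current_step": run.current_step,
                "step_delivered_ml": {str(k): v
                                      for k, v in run.step_delivered_ml.items()},
                "t_min": self.controller.clock.t_min}

    def _dispatch(self, chan: LineChannel, msg: Message) -> dict:
        cmd, args = msg.command, msg.args
        ctl, eng = self.controller, self.engine
        if ctl.config is None and cmd not in _PRE_CONFIG_COMMANDS:
            raise ConfigurationError(
                "no configuration selected; select_config must come first")

        if cmd == "select_config":
            state = ctl.load_configuration(args["name"])
            self.engine = ProtocolEngine(self.controller)
            return {"config": state.active_config,
                    "n_channels": ctl.n_channels}
        if cmd == "reset_config":
            ctl.reset()
            self.engine = ProtocolEngine(self.controller)
            return {"config": None}
        if cmd == "list_configs":
            return {"configs": self.registry.names()}
        if cmd == "status":
            payload = self._status_payload()
            if ctl.config is not None:
                payload.update(self._run_status())
            return payload
        if cmd == "set_flow_path":
            state = ctl.set_flow_path(args["channel"],
                                      _source_from_wire(args["source"]),
                                      FlowSink(args["sink"]))
            return {"rotary_port": state.rotary_port}
        if cmd == "run_pump":
            res = ctl.run_pump(args["channel"], args["volume_ml"],
                               args["rate_ml_min"])
            eng.ledger.add_pumped(res.channel, res.delivered_ml)
            eng.ledger.add_waste(res.channel, res.route.sink,
                                 res.delivered_ml, res.route.source.label)
            return {"delivered_ml": res.delivered_ml,
                    "duration_min": res.duration_min, "steps": res.steps}
        if cmd == "goto_fraction":
            state = ctl.goto_fraction(args["row"])
            return {"collector_row": state.collector_row}
        if cmd == "stop_all":
            ctl.stop_all()
            return {"stopped": True}
        if cmd == "calibrate":
            channels = args.get("channels") or list(range(1, ctl.n_channels + 1))
            factors = {}
            for ch in channels:
                model = eng.calibrate_flow(
                    ch, args.get("target_rate_cv_per_min", 1.0),
                    args.get("window_min", 1.0))
                factors[str(ch)] = model.volume_per_step_ul
            return {"volume_per_step_ul": factors}
        if cmd == "run_step":
            step = ProtocolStep.model_validate(args["step"])
            ledger = eng.run_step(
                step, channels=args.get("channels"),
                overrides=_int_keys(args.get("overrides")),
                control=self._make_control(chan, msg.request_id))
            return {"run_state": eng.run.state.value,
                    "ledger": ledger.to_dict()}
        if cmd == "run_protocol":
            if "protocol" in args:
                proto = Protocol.model_validate(args["protocol"])
            else:
                proto = get_protocol(args["protocol_name"])
            plan = eng.compile(proto, channels=args.get("channels"),
                               overrides=_int_keys(args.get("overrides")))
            ledger = eng.execute(
                plan, control=self._make_control(chan, msg.request_id))
            return {"run_state": eng.run.state.value,
                    "ledger": ledger.to_dict()}
        if cmd == "ledger":
            return {"ledger": eng.ledger.to_dict()}
        if cmd == "summary":
            return {"summary": eng.ledger.summary()}
        if cmd in _RUN_CONTROL_COMMANDS:
            raise RunStateError(f"no run in progress for {cmd!r}")
        raise ValidationError(f"unknown command {cmd!r}")

    def _make_control(self, chan: LineChannel, outer_id: int):
        """Control callback: streams progress and services nested requests."""
        counter = {"n": 0}

        def control(run) -> None:
            counter["n"] += 1
            blocked = run.state in (RunState.PAUSED, RunState.HOLDING)
            if counter["n"] % 10 == 1 or blocked:
                self._send(chan, Message(msg_type="STATUS",
                                         request_id=outer_id,
                                         payload=self._run_status()))
            line = chan.recv_line(timeout=0.05 if blocked else 0.0)
            if line is None:
                # connection lost mid-run (or forced disconnect): abort safely
                logger.warning("client vanished mid-run; aborting")
                try:
                    run.abort()
                except RunStateError:
                    pass
                raise ClientGone
            if line:
                self._handle_request(chan, line, nested=True)

        return control


def _int_keys(d: Optional[dict]) -> Optional[dict]:
    if d is None:
        return None
    return {int(k): v for k, v in d.items()}
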
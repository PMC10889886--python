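"""Compilation and execution of CV-denominated purification protocols.

A purification protocol is an ordered list of steps — equilibrate, load,
wash, elute, purge, hold — whose volumes and rates are written in column
volumes (CV) so one protocol file scales across 1 mL and 5 mL columns.  The
engine compiles a protocol against the active rig configuration into
absolute commands (mL, mL/min, collector rows, valve plans) and executes it
across up to four channels in lockstep: buffer-fed steps are global (one
shared rotary valve), load steps are channel-private and may carry
per-channel volume overrides.

Elution steps expand into per-fraction dispense + carriage-advance commands;
tubes may be pre-loaded by the operator with a neutralizing prefill (e.g.
0.15 CV of 1 M Tris pH 9.0 under low-pH antibody elution), which the ledger
records but the machine never dispenses.

Every run writes a :class:`RunLedger`: one record per collected fraction
(volume, prefill, source composition), waste totals per sink, total pumped
volume per channel, and an event log on the simulated clock.  When pump
noise is off the ledger is exactly volume-conserving.
"""

from __future__ import annotations

import enum
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional

import pandas as pd
import pydantic
import yaml

from . import fluidics
from .control import HardwareController, RigConfig
from .errors import (
    CalibrationError,
    CompileError,
    ProtocolFileError,
    RunStateError,
)
from .fluidics import FlowSink, FlowSource
from .virtual import PumpModel

#: all protocol steps default to this rate; purifications in the shipped
#: protocols are calibrated to it at the start of a run
DEFAULT_RATE_CV_PER_MIN = 1.0


class StepKind(enum.Enum):
    EQUILIBRATE = "equilibrate"
    LOAD = "load"
    WASH = "wash"
    ELUTE = "elute"
    PURGE = "purge"
    HOLD = "hold"


_BUFFER_FED = {StepKind.EQUILIBRATE, StepKind.WASH, StepKind.ELUTE, StepKind.PURGE}


class ProtocolStep(pydantic.BaseModel):
    """One CV-denominated step of a purification protocol."""

    kind: StepKind
    buffer_port: Optional[int] = None
    volume_cv: float = 0.0
    rate_cv_per_min: float = pydantic.Field(default=DEFAULT_RATE_CV_PER_MIN, gt=0.0)
    fraction_size_cv: Optional[float] = None   # ELUTE only
    prefill_cv: float = pydantic.Field(default=0.0, ge=0.0)  # ELUTE only
    collect_flowthrough: bool = False          # LOAD only

    model_config = pydantic.ConfigDict(extra="forbid")

    @pydantic.model_validator(mode="after")
    def _check(self):
        if self.kind is StepKind.HOLD:
            if self.volume_cv:
                raise ValueError("hold steps pump no volume")
            return self
        if self.volume_cv <= 0:
            raise ValueError(f"{self.kind.value}: volume_cv must be positive")
        if self.kind in _BUFFER_FED:
            if self.buffer_port is None:
                raise ValueError(f"{self.kind.value}: buffer_port required")
            if not 1 <= self.buffer_port <= fluidics.N_BUFFER_PORTS:
                raise ValueError(
                    f"buffer port {self.buffer_port} outside "
                    f"1..{fluidics.N_BUFFER_PORTS}")
        else:
            if self.buffer_port is not None:
                raise ValueError(f"{self.kind.value}: takes no buffer_port")
        if self.kind is StepKind.ELUTE:
            if not self.fraction_size_cv or self.fraction_size_cv <= 0:
                raise ValueError("elute: fraction_size_cv must be positive")
        else:
            if self.fraction_size_cv is not None:
                raise ValueError(f"{self.kind.value}: takes no fraction_size_cv")
            if self.prefill_cv:
                raise ValueError(f"{self.kind.value}: takes no prefill_cv")
        if self.collect_flowthrough and self.kind is not StepKind.LOAD:
            raise ValueError("collect_flowthrough applies to load steps only")
        return self

    @property
    def n_fractions(self) -> int:
        if self.kind is not StepKind.ELUTE:
            return 0
        return math.ceil(self.volume_cv / self.fraction_size_cv - 1e-9)


class Protocol(pydantic.BaseModel):
    """A named, ordered purification program with optional load overrides."""

    name: str
    description: str = ""
    steps: List[ProtocolStep]
    load_overrides: Dict[int, float] = pydantic.Field(default_factory=dict)

    model_config = pydantic.ConfigDict(extra="forbid")

    @pydantic.field_validator("load_overrides")
    @classmethod
    def _check_overrides(cls, v):
        for ch, cv in v.items():
            if not 1 <= ch <= fluidics.MAX_CHANNELS:
                raise ValueError(f"override channel {ch} outside 1..4")
            if cv <= 0:
                raise ValueError("override load volume must be positive")
        return v


def load_protocol(path: Path) -> Protocol:
    """Parse and validate a protocol file (YAML)."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ProtocolFileError(f"{path}: invalid YAML: {exc}") from exc
    try:
        return Protocol.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ProtocolFileError(f"{path}: {exc}") from exc


def shipped_protocols() -> Dict[str, Protocol]:
    """Protocols shipped with the package, keyed by name."""
    out: Dict[str, Protocol] = {}
    pkg_dir = importlib.resources.files("quadpure") / "protocols"
    for entry in sorted(pkg_dir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            proto = Protocol.model_validate(yaml.safe_load(entry.read_text()))
            out[proto.name] = proto
    return out


def get_protocol(name: str) -> Protocol:
    protocols = shipped_protocols()
    try:
        return protocols[name]
    except KeyError:
        raise ProtocolFileError(
            f"unknown protocol {name!r}; shipped: {sorted(protocols)}") from None


# ---------------------------------------------------------------------------
# Compiled plan


@dataclass(frozen=True)
class FractionSpec:
    index: int              # 1-based fraction number within the elution
    row: int                # collector row (shared across channels)
    volume_ml: Dict[int, float]     # per channel
    prefill_ml: Dict[int, float]    # per channel


@dataclass(frozen=True)
class CompiledStep:
    index: int
    kind: StepKind
    sources: Dict[int, FlowSource]
    sink: FlowSink
    volume_ml: Dict[int, float]
    rate_ml_min: Dict[int, float]
    fractions: tuple[FractionSpec, ...] = ()
    flowthrough_row: Optional[int] = None


@dataclass(frozen=True)
class CompiledPlan:
    protocol_name: str
    channels: tuple[int, ...]
    steps: tuple[CompiledStep, ...]
    small_rows_used: tuple[int, ...]
    large_rows_used: tuple[int, ...]

    def total_volume_ml(self, channel: int) -> float:
        return sum(s.volume_ml.get(channel, 0.0) for s in self.steps)


def compile_protocol(protocol: Protocol, rig_config: RigConfig,
                     channels: Optional[List[int]] = None,
                     overrides: Optional[Dict[int, float]] = None,
                     start_small_row: int = 1,
                     start_large_row: Optional[int] = None) -> CompiledPlan:
    """Compile a CV-denominated protocol into absolute hardware commands.

    ``channels`` selects a subset of the configured channels (default all);
    ``overrides`` are call-time per-channel load volumes in CV, taking
    precedence over the protocol's own ``load_overrides``.  Row allocation
    starts at the given cursors so stepwise execution of a protocol assigns
    the same rows as a single compiled run.

    Raises
    ------
    CompileError
        For buffer ports the rig does not define, more elution fractions
        than free small rows, flow-through capture without a free large row,
        or compiled rates outside the pump flow envelope.
    """
    plate = rig_config.plate_layout()
    if start_large_row is None:
        start_large_row = plate.small_rows + 1
    if channels is None:
        channels = list(range(1, rig_config.n_channels + 1))
    for ch in channels:
        fluidics.validate_channel(ch, rig_config.n_channels)
    if not channels:
        raise CompileError("no channels selected")

    load_cv = dict(protocol.load_overrides)
    load_cv.update(overrides or {})
    for ch in load_cv:
        if ch not in channels:
            raise CompileError(f"load override for unselected channel {ch}")

    cv = {ch: rig_config.column_volume_ml(ch) for ch in channels}
    steps: list[CompiledStep] = []
    small_rows: list[int] = []
    large_rows: list[int] = []
    next_small = start_small_row
    next_large = start_large_row

    for i, step in enumerate(protocol.steps, start=1):
        rate = {ch: step.rate_cv_per_min * cv[ch] for ch in channels}
        for ch in channels:
            fmax = rig_config.channels[ch - 1].pump
            model = PumpModel(volume_per_step_ul=fmax.volume_per_step_ul)
            if rate[ch] > model.flow_max_ml_min:
                raise CompileError(
                    f"step {i} ({step.kind.value}): rate {rate[ch]:.3g} mL/min "
                    f"on channel {ch} exceeds pump ceiling "
                    f"{model.flow_max_ml_min} mL/min")

        if step.kind is StepKind.HOLD:
            steps.append(CompiledStep(
                index=i, kind=step.kind, sources={}, sink=FlowSink.POST_COLUMN_WASTE,
                volume_ml={}, rate_ml_min=rate))
            continue

        if step.kind in _BUFFER_FED:
            if step.buffer_port not in rig_config.buffer_labels:
                raise CompileError(
                    f"step {i} ({step.kind.value}): buffer port "
                    f"{step.buffer_port} not defined in config "
                    f"{rig_config.name!r}")
            sources = {ch: FlowSource.buffer(step.buffer_port) for ch in channels}
        else:
            sources = {ch: FlowSource.load(ch) for ch in channels}

        if step.kind is StepKind.LOAD:
            vol_cv = {ch: load_cv.get(ch, step.volume_cv) for ch in channels}
        else:
            vol_cv = {ch: step.volume_cv for ch in channels}
        volume_ml = {ch: vol_cv[ch] * cv[ch] for ch in channels}

        sink = {
            StepKind.EQUILIBRATE: FlowSink.POST_COLUMN_WASTE,
            StepKind.WASH: FlowSink.POST_COLUMN_WASTE,
            StepKind.PURGE: FlowSink.PRE_COLUMN_WASTE,
            StepKind.LOAD: (FlowSink.FRACTION_COLLECTOR
                            if step.collect_flowthrough
                            else FlowSink.POST_COLUMN_WASTE),
            StepKind.ELUTE: FlowSink.FRACTION_COLLECTOR,
        }[step.kind]

        fractions: tuple[FractionSpec, ...] = ()
        flowthrough_row = None

        if step.kind is StepKind.ELUTE:
            n_frac = step.n_fractions
            if next_small + n_frac - 1 > plate.small_rows:
                raise CompileError(
                    f"step {i}: {n_frac} elution fractions need rows "
                    f"{next_small}..{next_small + n_frac - 1} but the plate "
                    f"has only {plate.small_rows} small rows")
            specs = []
            for f in range(1, n_frac + 1):
                frac_cv = min(step.fraction_size_cv,
                              step.volume_cv - (f - 1) * step.fraction_size_cv)
                specs.append(FractionSpec(
                    index=f, row=next_small,
                    volume_ml={ch: frac_cv * cv[ch] for ch in channels},
                    prefill_ml={ch: step.prefill_cv * cv[ch] for ch in channels},
                ))
                small_rows.append(next_small)
                next_small += 1
            fractions = tuple(specs)
        elif step.kind is StepKind.LOAD and step.collect_flowthrough:
            if next_large > plate.n_rows:
                raise CompileError(
                    f"step {i}: no free large (flow-through) row left")
            flowthrough_row = next_large
            large_rows.append(next_large)
            next_large += 1

        steps.append(CompiledStep(
            index=i, kind=step.kind, sources=sources, sink=sink,
            volume_ml=volume_ml, rate_ml_min=rate, fractions=fractions,
            flowthrough_row=flowthrough_row))

    return CompiledPlan(
        protocol_name=protocol.name, channels=tuple(channels),
        steps=tuple(steps), small_rows_used=tuple(small_rows),
        large_rows_used=tuple(large_rows))


# ---------------------------------------------------------------------------
# Ledger


@dataclass
class FractionRecord:
    """Audited contents of one collected tube."""

    channel: int
    row: int
    fraction_index: int          # 1-based within its elution (0 = flow-through)
    tube_capacity_ml: float
    dispensed_ml: float = 0.0    # total sent to the tube (incl. any overflow)
    prefill_ml: float = 0.0      # operator-loaded neutralizer, never pumped
    spilled_ml: float = 0.0      # overflow diverted to the spill bucket
    composition: Dict[str, float] = field(default_factory=dict)

    @property
    def in_tube_ml(self) -> float:
        return self.dispensed_ml - self.spilled_ml + self.prefill_ml

    @property
    def spilled(self) -> bool:
        return self.spilled_ml > 0

    def add(self, source_label: str, volume_ml: float) -> None:
        free = self.tube_capacity_ml - self.prefill_ml - (
            self.dispensed_ml - self.spilled_ml)
        overflow = max(0.0, volume_ml - free)
        self.dispensed_ml += volume_ml
        self.spilled_ml += overflow
        self.composition[source_label] = (
            self.composition.get(source_label, 0.0) + volume_ml)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel, "row": self.row,
            "fraction_index": self.fraction_index,
            "tube_capacity_ml": self.tube_capacity_ml,
            "dispensed_ml": self.dispensed_ml, "prefill_ml": self.prefill_ml,
            "spilled_ml": self.spilled_ml, "composition": dict(self.composition),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FractionRecord":
        return cls(channel=d["channel"], row=d["row"],
                   fraction_index=d["fraction_index"],
                   tube_capacity_ml=d["tube_capacity_ml"],
                   dispensed_ml=d["dispensed_ml"], prefill_ml=d["prefill_ml"],
                   spilled_ml=d["spilled_ml"],
                   composition=dict(d["composition"]))


@dataclass
class LedgerEvent:
    t_min: float
    channel: int
    step_index: int
    kind: str
    detail: str


@dataclass
class RunLedger:
    """Complete audit of where every pumped millilitre went."""

    fractions: List[FractionRecord] = field(default_factory=list)
    waste_ml: Dict[tuple[int, str], float] = field(default_factory=dict)
    #: waste attributed to the source that produced it (buffer:N / load:chN)
    waste_by_source_ml: Dict[tuple[int, str], float] = field(default_factory=dict)
    pumped_ml: Dict[int, float] = field(default_factory=dict)
    events: List[LedgerEvent] = field(default_factory=list)

    def add_waste(self, channel: int, sink: FlowSink, volume_ml: float,
                  source_label: str = "?") -> None:
        key = (channel, sink.value)
        self.waste_ml[key] = self.waste_ml.get(key, 0.0) + volume_ml
        skey = (channel, source_label)
        self.waste_by_source_ml[skey] = (
            self.waste_by_source_ml.get(skey, 0.0) + volume_ml)

    def add_pumped(self, channel: int, volume_ml: float) -> None:
        self.pumped_ml[channel] = self.pumped_ml.get(channel, 0.0) + volume_ml

    def log(self, t_min: float, channel: int, step_index: int,
            kind: str, detail: str) -> None:
        self.events.append(LedgerEvent(t_min, channel, step_index, kind, detail))

    # -- queries ------------------------------------------------------------

    def channel_fractions(self, channel: int,
                          elution_only: bool = False) -> List[FractionRecord]:
        return [f for f in self.fractions if f.channel == channel
                and (not elution_only or f.fraction_index > 0)]

    def channel_waste_ml(self, channel: int, sink: Optional[FlowSink] = None) -> float:
        return sum(v for (ch, s), v in self.waste_ml.items()
                   if ch == channel and (sink is None or s == sink.value))

    def source_waste_ml(self, channel: int, source_label: str) -> float:
        """Waste volume attributed to one source on one channel."""
        return self.waste_by_source_ml.get((channel, source_label), 0.0)

    def conservation_residual_ml(self, channel: int) -> float:
        """pumped − (Σ fraction dispensed + Σ waste); 0 when noiseless."""
        dispensed = sum(f.dispensed_ml for f in self.channel_fractions(channel))
        return (self.pumped_ml.get(channel, 0.0)
                - dispensed - self.channel_waste_ml(channel))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fractions": [f.to_dict() for f in self.fractions],
            "waste_ml": {f"{ch}:{sink}": v
                         for (ch, sink), v in self.waste_ml.items()},
            "waste_by_source_ml": {f"{ch}:{label}": v
                                   for (ch, label), v
                                   in self.waste_by_source_ml.items()},
            "pumped_ml": {str(ch): v for ch, v in self.pumped_ml.items()},
            "events": [[e.t_min, e.channel, e.step_index, e.kind, e.detail]
                       for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunLedger":
        ledger = cls()
        ledger.fractions = [FractionRecord.from_dict(f) for f in d["fractions"]]
        for key, v in d["waste_ml"].items():
            ch, sink = key.split(":", 1)
            ledger.waste_ml[(int(ch), sink)] = v
        for key, v in d.get("waste_by_source_ml", {}).items():
            ch, label = key.split(":", 1)
            ledger.waste_by_source_ml[(int(ch), label)] = v
        ledger.pumped_ml = {int(ch): v for ch, v in d["pumped_ml"].items()}
        ledger.events = [LedgerEvent(*e) for e in d["events"]]
        return ledger

    def to_dataframe(self) -> pd.DataFrame:
        """One row per fraction and per waste total (for CSV export)."""
        rows = []
        for f in self.fractions:
            rows.append({
                "record": "fraction", "channel": f.channel, "row": f.row,
                "fraction_index": f.fraction_index,
                "volume_ml": f.dispensed_ml, "prefill_ml": f.prefill_ml,
                "spilled_ml": f.spilled_ml,
                "composition": "; ".join(
                    f"{k}={v:.4g}" for k, v in sorted(f.composition.items())),
            })
        for (ch, sink), v in sorted(self.waste_ml.items()):
            rows.append({"record": "waste", "channel": ch, "row": None,
                         "fraction_index": None, "volume_ml": v,
                         "prefill_ml": 0.0, "spilled_ml": 0.0,
                         "composition": sink})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        for ch in sorted(self.pumped_ml):
            lines.append(f"channel {ch}: pumped {self.pumped_ml[ch]:.3f} mL, "
                         f"waste {self.channel_waste_ml(ch):.3f} mL, "
                         f"{len(self.channel_fractions(ch, elution_only=True))}"
                         f" elution fraction(s)")
            for f in self.channel_fractions(ch):
                tag = ("flow-through" if f.fraction_index == 0
                       else f"fraction {f.fraction_index}")
                spill = f" SPILLED {f.spilled_ml:.3f} mL" if f.spilled else ""
                lines.append(
                    f"  row {f.row:2d} {tag}: {f.dispensed_ml:.3f} mL"
                    f" (+{f.prefill_ml:.3f} mL prefill){spill}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Run state machine


class RunState(enum.Enum):
    IDLE = "idle"
    RUNNING = "running"
    HOLDING = "holding"
    PAUSED = "paused"
    ABORTED = "aborted"
    COMPLETE = "complete"


class RunHandle:
    """Operator control of an executing run: pause, hold, resume, abort.

    Legal transitions: RUNNING↔PAUSED, RUNNING→HOLDING→RUNNING (hold lets
    the current step finish, then idles awaiting resume), and any active
    state →ABORTED.
    """

    def __init__(self) -> None:
        self.state = RunState.IDLE
        self.current_step: Optional[int] = None
        self.step_delivered_ml: Dict[int, float] = {}
        self.hold_requested = False

    def pause(self) -> RunState:
        if self.state is not RunState.RUNNING:
            raise RunStateError(f"cannot pause from {self.state.value}")
        self.state = RunState.PAUSED
        return self.state

    def resume(self) -> RunState:
        if self.state not in (RunState.PAUSED, RunState.HOLDING):
            raise RunStateError(f"cannot resume from {self.state.value}")
        self.state = RunState.RUNNING
        return self.state

    def hold(self) -> RunState:
        """Finish the current step, then wait for the operator."""
        if self.state is not RunState.RUNNING:
            raise RunStateError(f"cannot hold from {self.state.value}")
        self.hold_requested = True
        return self.state

    def abort(self) -> RunState:
        if self.state not in (RunState.RUNNING, RunState.PAUSED, RunState.HOLDING):
            raise RunStateError(f"cannot abort from {self.state.value}")
        self.state = RunState.ABORTED
        return self.state


#: control callback signature: called between dispense quanta and while the
#: run is paused/holding; may call pause/resume/hold/abort on the handle
ControlFn = Callable[[RunHandle], None]


# ---------------------------------------------------------------------------
# Engine


class ProtocolEngine:
    """Executes compiled plans on a hardware controller, keeping one
    cumulative session ledger and the collector-row cursors, so a protocol
    run as a single plan and the same protocol run step-by-step through
    client wrappers allocate identical rows and produce identical ledgers.

    ``tick_cv`` sets the dispense quantum (in CV) between control points;
    pause/abort take effect at quantum boundaries and resume completes the
    remaining volume exactly.
    """

    def __init__(self, controller: HardwareController, tick_cv: float = 0.5) -> None:
        if tick_cv <= 0:
            raise ValueError("tick_cv must be positive")
        self.controller = controller
        self.tick_cv = tick_cv
        self.ledger = RunLedger()
        self.next_small_row = 1
        self.next_large_row: Optional[int] = None   # set on first compile
        self.run = RunHandle()

    # -- compile ------------------------------------------------------------

    def compile(self, protocol: Protocol,
                channels: Optional[List[int]] = None,
                overrides: Optional[Dict[int, float]] = None) -> CompiledPlan:
        cfg = self.controller.config
        if cfg is None:
            raise CompileError("no configuration loaded")
        if self.next_large_row is None:
            self.next_large_row = cfg.plate_layout().small_rows + 1
        return compile_protocol(protocol, cfg, channels=channels,
                                overrides=overrides,
                                start_small_row=self.next_small_row,
                                start_large_row=self.next_large_row)

    # -- execute ------------------------------------------------------------

    def execute(self, plan: CompiledPlan,
                control: Optional[ControlFn] = None) -> RunLedger:
        """Run a compiled plan to completion (or abort); returns the session
        ledger.  On any hardware error the run aborts to a safe state with
        the ledger preserved, and the error propagates."""
        ctl = self.controller
        if ctl.config is None:
            raise CompileError("no configuration loaded")
        run = self.run = RunHandle()
        run.state = RunState.RUNNING
        plate = ctl.plate
        try:
            for step in plan.steps:
                run.current_step = step.index
                run.step_delivered_ml = {ch: 0.0 for ch in plan.channels}
                if run.state is RunState.ABORTED:
                    break
                if step.kind is StepKind.HOLD:
                    self._enter_hold(run, control, step.index)
                    continue
                self._run_step(plan, step, plate, run, control)
                if run.state is RunState.ABORTED:
                    break
                if run.hold_requested:
                    run.hold_requested = False
                    self._enter_hold(run, control, step.index)
            if run.state is not RunState.ABORTED:
                run.state = RunState.COMPLETE
        except Exception:
            run.state = RunState.ABORTED
            ctl.stop_all()
            raise
        finally:
            if run.state is RunState.ABORTED:
                ctl.stop_all()
        # row cursors only advance for rows the plan actually touched
        if plan.small_rows_used:
            self.next_small_row = max(self.next_small_row,
                                      max(plan.small_rows_used) + 1)
        if plan.large_rows_used:
            self.next_large_row = max(self.next_large_row or 0,
                                      max(plan.large_rows_used) + 1)
        return self.ledger

    def run_step(self, step: ProtocolStep,
                 channels: Optional[List[int]] = None,
                 overrides: Optional[Dict[int, float]] = None,
                 control: Optional[ControlFn] = None) -> RunLedger:
        """Compile and execute a single step (client wrapper entry point)."""
        proto = Protocol(name=f"step:{step.kind.value}", steps=[step])
        return self.execute(self.compile(proto, channels, overrides), control)

    # -- internals ----------------------------------------------------------

    def _enter_hold(self, run: RunHandle, control: Optional[ControlFn],
                    step_index: int) -> None:
        run.state = RunState.HOLDING
        self.ledger.log(self.controller.clock.t_min, 0, step_index,
                        "hold", "holding; awaiting operator resume")
        if control is None:
            # nobody can resume us; treat as a completed hold point
            run.state = RunState.RUNNING
            return
        while run.state is RunState.HOLDING:
            control(run)
        if run.state is RunState.ABORTED:
            return

    def _control_point(self, run: RunHandle, control: Optional[ControlFn]) -> None:
        if control is not None:
            control(run)
        while run.state is RunState.PAUSED:
            if control is None:
                raise RunStateError("run paused with no controller attached")
            control(run)

    def _run_step(self, plan: CompiledPlan, step: CompiledStep, plate,
                  run: RunHandle, control: Optional[ControlFn]) -> None:
        ctl = self.controller
        clock = ctl.clock
        for ch in plan.channels:
            ctl.park_channel(ch)
        for ch in plan.channels:
            ctl.set_flow_path(ch, step.sources[ch], step.sink)
        self.ledger.log(clock.t_min, 0, step.index, step.kind.value,
                        f"routes set, sink={step.sink.value}")

        tick_ml = {ch: self.tick_cv * ctl.config.column_volume_ml(ch)
                   for ch in plan.channels}

        if step.kind is StepKind.ELUTE:
            for frac in step.fractions:
                if run.state is RunState.ABORTED:
                    return
                ctl.goto_fraction(frac.row)
                records = {}
                for ch in plan.channels:
                    rec = FractionRecord(
                        channel=ch, row=frac.row, fraction_index=frac.index,
                        tube_capacity_ml=plate.tube_capacity_ml(frac.row),
                        prefill_ml=frac.prefill_ml[ch])
                    self.ledger.fractions.append(rec)
                    records[ch] = rec
                self._dispense_tracked(
                    plan, step, {ch: frac.volume_ml[ch] for ch in plan.channels},
                    tick_ml, run, control,
                    recorder=lambda ch, lbl, v, recs=records: recs[ch].add(lbl, v))
        else:
            if step.flowthrough_row is not None:
                ctl.goto_fraction(step.flowthrough_row)
                records = {}
                for ch in plan.channels:
                    rec = FractionRecord(
                        channel=ch, row=step.flowthrough_row, fraction_index=0,
                        tube_capacity_ml=plate.tube_capacity_ml(step.flowthrough_row))
                    self.ledger.fractions.append(rec)
                    records[ch] = rec
                recorder = (lambda ch, lbl, v, recs=records: recs[ch].add(lbl, v))
            else:
                recorder = (lambda ch, lbl, v, sink=step.sink:
                            self.ledger.add_waste(ch, sink, v, lbl))
            self._dispense_tracked(plan, step, dict(step.volume_ml), tick_ml,
                                   run, control, recorder=recorder)

    def _dispense_tracked(self, plan: CompiledPlan, step: CompiledStep,
                          remaining_ml: Dict[int, float],
                          tick_ml: Dict[int, float], run: RunHandle,
                          control: Optional[ControlFn],
                          recorder: Callable[[int, str, float], None]) -> None:
        ctl = self.controller
        eps = 1e-12
        while any(v > eps for v in remaining_ml.values()):
            self._control_point(run, control)
            if run.state is RunState.ABORTED:
                return
            vols = {ch: min(tick_ml[ch], rem)
                    for ch, rem in remaining_ml.items() if rem > eps}
            results = ctl.dispense_parallel(
                vols, {ch: step.rate_ml_min[ch] for ch in vols})
            for ch, res in results.items():
                remaining_ml[ch] -= vols[ch]
                run.step_delivered_ml[ch] = (
                    run.step_delivered_ml.get(ch, 0.0) + res.delivered_ml)
                self.ledger.add_pumped(ch, res.delivered_ml)
                recorder(ch, res.route.source.label, res.delivered_ml)

    # -- calibration --------------------------------------------------------

    def calibrate_flow(self, channel: int,
                       target_rate_cv_per_min: float = DEFAULT_RATE_CV_PER_MIN,
                       measurement_window_min: float = 1.0,
                       n_windows: int = 5) -> PumpModel:
        """Coarse step-to-volume calibration of one channel's pump.

        Commands the pump to deliver ``target_rate × CV × window`` for each
        of ``n_windows`` timed windows and compares the mean measured
        (simulated-balance) volume with the target; the believed µL-per-step
        factor is scaled by measured/target, so a perfectly measured pump is
        a fixed point and a mis-scaled pump is corrected in one pass
        (exactly when noiseless).  Averaging several windows keeps the
        calibration bias well below the per-aliquot noise sd.  The channel's
        route must already point at a measurable sink.
        """
        ctl = self.controller
        if ctl.config is None:
            raise CalibrationError("no configuration loaded")
        if measurement_window_min <= 0:
            raise CalibrationError("measurement window must be positive")
        if n_windows < 1:
            raise CalibrationError("n_windows must be at least 1")
        cv = ctl.config.column_volume_ml(channel)
        target_ml = target_rate_cv_per_min * cv * measurement_window_min
        rate_ml_min = target_rate_cv_per_min * cv
        total = 0.0
        for _ in range(n_windows):
            result = ctl.run_pump(channel, target_ml, rate_ml_min)
            total += result.delivered_ml
            self.ledger.add_pumped(channel, result.delivered_ml)
            self.ledger.add_waste(channel, result.route.sink,
                                  result.delivered_ml,
                                  result.route.source.label)
        measured = total / n_windows
        if measured <= 0:
            raise CalibrationError(
                f"channel {channel}: measured volume {measured} mL")
        model = ctl.pump_model(channel)
        new_factor = model.volume_per_step_ul * (measured / target_ml)
        self.ledger.log(ctl.clock.t_min, channel, 0, "calibrate",
                        f"measured {measured:.4f} mL for {target_ml:.4f} mL "
                        f"target; volume_per_step {model.volume_per_step_ul:.5f}"
                        f" -> {new_factor:.5f} µL")
        return ctl.apply_calibration(channel, new_factor)
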
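"""Hardware controller and named rig configurations.

The controller is the layer between protocol logic and peripherals: it owns
the (simulated) I2C bus, instantiates one driver per device when a named
configuration is loaded, and exposes the operationally significant commands
— set a flow path, run a pump for a volume at a rate, move the fraction
collector, stop everything.  Rig configurations are structured-text (YAML)
documents naming the column sizes, buffer labels, collector plate variant
and bus addresses; a client selects one by name before any hardware command
is accepted, and it persists until the client disconnects or resets it.

The controller never touches relays or steppers directly: every actuation is
a bus transaction, so any bus implementation honouring the same device
contract (including a real hardware backend) can stand behind it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pydantic
import yaml

from . import fluidics
from .errors import (
    ConfigurationError,
    ProtocolFileError,
    PumpCommandError,
    SharedBufferConflictError,
    ValidationError,
)
from .fluidics import (
    FlowSink,
    FlowSource,
    RouteState,
    SolenoidRole,
    SourceKind,
    valve_plan,
)
from .virtual import (
    ActuatorDevice,
    PlateLayout,
    PumpDevice,
    PumpModel,
    RelayBoardDevice,
    RotaryValveDevice,
    SimClock,
    SimulatedBus,
    default_row_positions,
)

#: default 7-bit bus addresses; overridable per config file
DEFAULT_ADDRESSES = {
    "pumps": [0x10, 0x11, 0x12, 0x13],
    "relay_boards": [0x20, 0x21],
    "rotary": 0x30,
    "actuator": 0x40,
}

#: order in which each channel's three solenoids map onto relay outputs
_ROLE_ORDER = (
    SolenoidRole.INPUT_SELECT,
    SolenoidRole.PRE_COLUMN_PURGE,
    SolenoidRole.POST_COLUMN_SELECT,
)


# ---------------------------------------------------------------------------
# Configuration schema (pydantic -> YAML files)


class PumpSettings(pydantic.BaseModel):
    """Per-channel pump parameters as written in a rig config file.

    ``sim_scale_error`` is a simulation-only ground truth: the factor by
    which the virtual pump's real µL-per-step differs from the believed
    calibration factor (1.0 = perfectly calibrated).
    """

    volume_per_step_ul: float = 0.5
    noise_sd_rel: float = pydantic.Field(default=0.0, ge=0.0)
    sim_scale_error: float = pydantic.Field(default=1.0, gt=0.0)

    model_config = pydantic.ConfigDict(extra="forbid")


class ChannelConfig(pydantic.BaseModel):
    column_volume_ml: float = pydantic.Field(gt=0.0)
    column_type: str = "generic"
    pump: PumpSettings = pydantic.Field(default_factory=PumpSettings)

    model_config = pydantic.ConfigDict(extra="forbid")


class PlateSettings(pydantic.BaseModel):
    small_tube_ml: float = 1.5

    model_config = pydantic.ConfigDict(extra="forbid")


class RigConfig(pydantic.BaseModel):
    """A named hardware configuration (column sizes, buffers, plate, bus map)."""

    name: str
    description: str = ""
    channels: List[ChannelConfig]
    buffer_labels: Dict[int, str] = pydantic.Field(default_factory=dict)
    plate: PlateSettings = pydantic.Field(default_factory=PlateSettings)
    addresses: Dict[str, object] = pydantic.Field(default_factory=dict)

    model_config = pydantic.ConfigDict(extra="forbid")

    @pydantic.field_validator("channels")
    @classmethod
    def _check_channels(cls, v):
        if not 1 <= len(v) <= fluidics.MAX_CHANNELS:
            raise ValueError(
                f"rig must declare 1..{fluidics.MAX_CHANNELS} channels")
        return v

    @pydantic.field_validator("buffer_labels")
    @classmethod
    def _check_ports(cls, v):
        for port in v:
            if not 1 <= port <= fluidics.N_BUFFER_PORTS:
                raise ValueError(
                    f"buffer port {port} outside 1..{fluidics.N_BUFFER_PORTS}")
        return v

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def column_volume_ml(self, channel: int) -> float:
        fluidics.validate_channel(channel, self.n_channels)
        return self.channels[channel - 1].column_volume_ml

    def plate_layout(self) -> PlateLayout:
        return PlateLayout(small_tube_ml=self.plate.small_tube_ml)


def load_rig_config(path: Path) -> RigConfig:
    """Parse and validate a rig configuration file."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ProtocolFileError(f"{path}: invalid YAML: {exc}") from exc
    try:
        return RigConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ProtocolFileError(f"{path}: {exc}") from exc


class ConfigRegistry:
    """Named configurations shipped with the package plus user-supplied ones."""

    def __init__(self, extra_dir: Optional[Path] = None) -> None:
        self._configs: Dict[str, RigConfig] = {}
        pkg_dir = importlib.resources.files("quadpure") / "configs"
        for entry in sorted(pkg_dir.iterdir(), key=lambda e: e.name):
            if entry.name.endswith(".yaml"):
                cfg = RigConfig.model_validate(yaml.safe_load(entry.read_text()))
                self._configs[cfg.name] = cfg
        if extra_dir is not None:
            for path in sorted(Path(extra_dir).glob("*.yaml")):
                self.register(load_rig_config(path))

    def register(self, config: RigConfig) -> None:
        if config.name in self._configs:
            raise ConfigurationError(f"configuration {config.name!r} already registered")
        self._configs[config.name] = config

    def names(self) -> list[str]:
        return sorted(self._configs)

    def get(self, name: str) -> RigConfig:
        try:
            return self._configs[name]
        except KeyError:
            raise ConfigurationError(f"unknown configuration {name!r}") from None


# ---------------------------------------------------------------------------
# Controller


@dataclass
class DispenseResult:
    channel: int
    requested_ml: float
    delivered_ml: float
    duration_min: float
    steps: int
    route: RouteState


@dataclass
class DeliveryEvent:
    """Audit record: volume delivered to a channel's active sink."""

    t_min: float
    channel: int
    source_label: str
    sink: FlowSink
    delivered_ml: float


@dataclass
class ControllerState:
    active_config: Optional[str] = None
    routes: Dict[int, Optional[RouteState]] = field(default_factory=dict)
    rotary_port: Optional[int] = None
    collector_row: Optional[int] = None


class HardwareController:
    """Drives the peripherals of one rig through its bus.

    Lifecycle: construct with a registry, then :meth:`load_configuration`
    instantiates the drivers (valves parked safe, rotary homed, pumps idle).
    Commands are rejected until a configuration is active; the configuration
    persists until :meth:`reset` (or a client disconnect, which calls it).
    """

    def __init__(self, registry: Optional[ConfigRegistry] = None) -> None:
        self.registry = registry or ConfigRegistry()
        self.state = ControllerState()
        self.config: Optional[RigConfig] = None
        self.bus: Optional[SimulatedBus] = None
        self.clock = SimClock()
        self.deliveries: list[DeliveryEvent] = []
        self._pumps: Dict[int, PumpModel] = {}
        self._pump_devices: Dict[int, PumpDevice] = {}
        self._pump_busy: Dict[int, bool] = {}
        self._addresses: dict = {}
        self._plate: Optional[PlateLayout] = None
        self._graph: Optional[fluidics.FluidicGraph] = None

    # -- lifecycle ----------------------------------------------------------

    def load_configuration(self, name: str) -> ControllerState:
        if self.config is not None:
            raise ConfigurationError(
                f"configuration {self.config.name!r} already active; reset first")
        cfg = self.registry.get(name)

        addresses = dict(DEFAULT_ADDRESSES)
        addresses.update(cfg.addresses)
        self.bus = SimulatedBus(clock=self.clock)
        self._pump_devices = {}
        self._pumps = {}
        for ch, chan_cfg in enumerate(cfg.channels, start=1):
            model = PumpModel(
                volume_per_step_ul=chan_cfg.pump.volume_per_step_ul,
                noise_sd_rel=chan_cfg.pump.noise_sd_rel,
                seed=self._seed_for_channel(ch),
            )
            dev = PumpDevice(model, scale_error=chan_cfg.pump.sim_scale_error)
            self.bus.register_device(addresses["pumps"][ch - 1], dev)
            self._pumps[ch] = model
            self._pump_devices[ch] = dev
            self._pump_busy[ch] = False
        self._relay_addrs = list(addresses["relay_boards"])
        for addr in self._relay_addrs:
            self.bus.register_device(addr, RelayBoardDevice())
        self._rotary = RotaryValveDevice()
        self.bus.register_device(addresses["rotary"], self._rotary)
        self._plate = cfg.plate_layout()
        self._actuator = ActuatorDevice(default_row_positions(self._plate))
        self.bus.register_device(addresses["actuator"], self._actuator)
        self._addresses = addresses

        self.config = cfg
        self._graph = fluidics.build_graph(cfg.n_channels)
        self.state = ControllerState(
            active_config=cfg.name,
            routes={ch: None for ch in range(1, cfg.n_channels + 1)},
        )
        # safe defaults: all solenoids de-energized (sinks at waste), rotary homed
        for ch in range(1, cfg.n_channels + 1):
            self._apply_valves(ch, {role: False for role in SolenoidRole})
        self.bus.transact(addresses["rotary"], "home")
        self.state.rotary_port = self._rotary.current_port
        return self.state

    def reset(self) -> ControllerState:
        """Drop the active configuration (stop everything first)."""
        if self.config is not None:
            self.stop_all()
        self.config = None
        self.bus = None
        self._pumps = {}
        self._pump_devices = {}
        self.state = ControllerState()
        return self.state

    def _seed_for_channel(self, channel: int) -> int:
        return (getattr(self, "seed", 0) * 131 + channel) % (2**31)

    def set_seed(self, seed: int) -> None:
        """Seed for pump noise; must be set before load_configuration."""
        self.seed = int(seed)

    # -- guards -------------------------------------------------------------

    def _require_config(self) -> RigConfig:
        if self.config is None:
            raise ConfigurationError("no configuration loaded")
        return self.config

    @property
    def n_channels(self) -> int:
        return self._require_config().n_channels

    def pump_model(self, channel: int) -> PumpModel:
        self._require_config()
        fluidics.validate_channel(channel, self.n_channels)
        return self._pumps[channel]

    def pump_device(self, channel: int) -> PumpDevice:
        self._require_config()
        fluidics.validate_channel(channel, self.n_channels)
        return self._pump_devices[channel]

    @property
    def plate(self) -> PlateLayout:
        self._require_config()
        return self._plate

    # -- flow paths ---------------------------------------------------------

    def _relay_for(self, channel: int, role: SolenoidRole) -> tuple[int, int]:
        # 3 solenoids per channel laid out across stacked 8-relay boards
        idx = (channel - 1) * len(_ROLE_ORDER) + _ROLE_ORDER.index(role)
        board, relay = divmod(idx, RelayBoardDevice.N_RELAYS)
        return self._relay_addrs[board], relay

    def _apply_valves(self, channel: int, states: Dict[SolenoidRole, bool]) -> None:
        for role, on in states.items():
            addr, relay = self._relay_for(channel, role)
            self.bus.transact(addr, "set", relay=relay, on=on)

    def set_flow_path(self, channel: int, source: FlowSource,
                      sink: FlowSink) -> ControllerState:
        """Route a channel from ``source`` to ``sink``.

        A buffer source moves the shared rotary valve; because the rotary
        feeds all channels through one splitter, the request is refused with
        a conflict error if any other channel is currently engaged on a
        different buffer port.
        """
        cfg = self._require_config()
        fluidics.validate_channel(channel, cfg.n_channels)
        plan = valve_plan(source, sink, channel, self._graph)

        if source.kind is SourceKind.BUFFER:
            for other, route in self.state.routes.items():
                if other == channel or route is None:
                    continue
                if (route.source.kind is SourceKind.BUFFER
                        and route.source.buffer_port != source.buffer_port):
                    raise SharedBufferConflictError(
                        f"channel {other} is flowing from buffer port "
                        f"{route.source.buffer_port}; cannot move rotary to "
                        f"port {source.buffer_port} for channel {channel}")
            self.bus.transact(self._addresses["rotary"], "goto",
                              port=plan.rotary_port)
            self.state.rotary_port = plan.rotary_port

        self._apply_valves(channel, {v.role: v.energized for v in plan.valves})
        route = RouteState(channel=channel, source=source, sink=sink)
        self.state.routes[channel] = route
        return self.state

    def park_channel(self, channel: int) -> None:
        """Disengage a channel: all solenoids de-energized, no active route."""
        self._require_config()
        fluidics.validate_channel(channel, self.n_channels)
        self._apply_valves(channel, {role: False for role in SolenoidRole})
        self.state.routes[channel] = None

    # -- pumping ------------------------------------------------------------

    def _check_rate(self, channel: int, rate_ml_min: float) -> None:
        model = self._pumps[channel]
        if rate_ml_min > model.flow_max_ml_min:
            raise PumpCommandError(
                f"rate {rate_ml_min} mL/min above pump ceiling "
                f"{model.flow_max_ml_min} mL/min")
        if rate_ml_min < model.flow_min_ml_min:
            raise PumpCommandError(
                f"rate {rate_ml_min} mL/min below pump floor "
                f"{model.flow_min_ml_min} mL/min")

    def run_pump(self, channel: int, volume_ml: float,
                 rate_ml_min: float) -> DispenseResult:
        """Dispense ``volume_ml`` through a channel's active route."""
        return self.dispense_parallel({channel: volume_ml}, rate_ml_min)[channel]

    def dispense_parallel(self, volumes_ml: Dict[int, float],
                          rate_ml_min) -> Dict[int, DispenseResult]:
        """Dispense on several channels simultaneously.

        ``rate_ml_min`` may be a single rate or a per-channel map (channels
        with different column volumes run the same CV/min at different
        mL/min).  The virtual clock advances once, by the longest dispense
        duration, mirroring channels running in parallel in real time.
        """
        cfg = self._require_config()
        if not volumes_ml:
            raise PumpCommandError("no channels given")
        if not isinstance(rate_ml_min, dict):
            rate_ml_min = {ch: rate_ml_min for ch in volumes_ml}
        results: Dict[int, DispenseResult] = {}
        for channel, volume_ml in volumes_ml.items():
            fluidics.validate_channel(channel, cfg.n_channels)
            if volume_ml <= 0:
                raise PumpCommandError(
                    f"dispense volume must be positive, got {volume_ml}")
            self._check_rate(channel, rate_ml_min[channel])
            if self.state.routes.get(channel) is None:
                raise PumpCommandError(f"channel {channel}: no route set")
            if self._pump_busy[channel]:
                raise PumpCommandError(f"channel {channel}: pump busy")

        duration = max(v / rate_ml_min[ch] for ch, v in volumes_ml.items())
        for channel, volume_ml in volumes_ml.items():
            model = self._pumps[channel]
            steps = int(round(volume_ml / model.volume_per_step_ml))
            self._pump_busy[channel] = True
            try:
                resp = self.bus.transact(self._addresses["pumps"][channel - 1],
                                         "advance", steps=steps)
            finally:
                self._pump_busy[channel] = False
            delivered = resp["dispensed_ml"]
            route = self.state.routes[channel]
            self.deliveries.append(DeliveryEvent(
                t_min=self.clock.t_min, channel=channel,
                source_label=route.source.label, sink=route.sink,
                delivered_ml=delivered))
            results[channel] = DispenseResult(
                channel=channel, requested_ml=volume_ml, delivered_ml=delivered,
                duration_min=volume_ml / rate_ml_min[channel], steps=steps,
                route=route)
        self.clock.advance(duration)
        return results

    def apply_calibration(self, channel: int, new_volume_per_step_ul: float) -> PumpModel:
        """Install an updated step-to-volume calibration factor."""
        self._require_config()
        if new_volume_per_step_ul <= 0:
            raise ValidationError("calibration factor must be positive")
        self._pumps[channel].volume_per_step_ul = new_volume_per_step_ul
        return self._pumps[channel]

    # -- collector / safety -------------------------------------------------

    def goto_fraction(self, row: int) -> ControllerState:
        """Move the collector carriage under the given row (shared by all channels)."""
        self._require_config()
        self._plate.validate_row(row)
        self.bus.transact(self._addresses["actuator"], "goto_row", row=row)
        self.state.collector_row = row
        return self.state

    def stop_all(self) -> ControllerState:
        """Halt pumps and park every post-column valve at waste (idempotent)."""
        cfg = self._require_config()
        for ch in range(1, cfg.n_channels + 1):
            self.park_channel(ch)
            self._pump_busy[ch] = False
        return self.state
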
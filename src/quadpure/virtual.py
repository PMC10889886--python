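"""Simulated I2C bus and peripherals.

The real instrument hangs every peripheral off a single I2C bus driven by a
single-board computer: stackable 8-channel relay boards for the solenoid
valves, stepper drivers for the four 6-roller peristaltic pumps, the 8-port
rotary selection valve, and the linear-actuator fraction collector.  This
module reproduces that bus contract in software so the whole control stack
runs at desk scale: devices register at 7-bit addresses (at most 128 on one
bus), every transaction is logged, and time is a virtual clock advanced by
volume/rate instead of wall time.

The pump carries an optional synthetic noise model — an aliquot-wise
Gaussian relative error on each dispensed volume — so simulator experiments
can emulate the spread of real collected fractions.  It is a deliberately
simple stand-in for tubing elasticity and hydrostatic effects, seeded and
reproducible.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import BusError, DeviceStateError, ValidationError

BUS_ADDRESS_SPACE = 128          # 7-bit addressing: up to 128 unique devices
PUMP_ROLLERS = 6
PUMP_TUBING_ID_MM = 1.0
PUMP_FLOW_MIN_ML_MIN = 4e-6      # envelope at 1 mm inner-diameter tubing
PUMP_FLOW_MAX_ML_MIN = 21.0
ROTARY_PORTS = 8
SMALL_ROWS = 10                  # collector rows for 1.5 or 5 mL tubes
LARGE_ROWS = 4                   # collector rows for 50 mL tubes
TUBES_PER_ROW = 4                # one tube per channel


class SimClock:
    """Virtual clock, in simulated minutes."""

    def __init__(self) -> None:
        self.t_min = 0.0

    def advance(self, minutes: float) -> None:
        if minutes < 0:
            raise ValidationError("cannot advance the clock backwards")
        self.t_min += minutes


@dataclass
class Transaction:
    seq: int
    t_min: float
    address: int
    command: str
    args: dict
    response: dict


class SimulatedDevice:
    """Base contract every simulated peripheral implements."""

    def handle(self, command: str, args: dict) -> dict:
        raise NotImplementedError


class SimulatedBus:
    """A software I2C bus: an address map plus a full transaction log."""

    def __init__(self, clock: Optional[SimClock] = None) -> None:
        self.clock = clock or SimClock()
        self.devices: Dict[int, SimulatedDevice] = {}
        self.log: list[Transaction] = []

    def register_device(self, address: int, device: SimulatedDevice) -> SimulatedDevice:
        if not isinstance(address, int) or isinstance(address, bool):
            raise ValidationError(f"bus address must be an integer, got {address!r}")
        if not 0 <= address < BUS_ADDRESS_SPACE:
            raise ValidationError(
                f"bus address {address} outside 0..{BUS_ADDRESS_SPACE - 1}")
        if address in self.devices:
            raise BusError(f"address collision at 0x{address:02x}")
        if len(self.devices) >= BUS_ADDRESS_SPACE:
            raise BusError(f"bus full: {BUS_ADDRESS_SPACE} devices already registered")
        self.devices[address] = device
        return device

    def transact(self, address: int, command: str, **args) -> dict:
        if address not in self.devices:
            raise BusError(f"no device at 0x{address:02x}")
        response = self.devices[address].handle(command, args)
        self.log.append(Transaction(
            seq=len(self.log), t_min=self.clock.t_min, address=address,
            command=command, args=dict(args), response=dict(response)))
        return response

    def export_log_csv(self) -> str:
        """Render the transaction log as CSV text (debugging aid)."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["seq", "t_min", "address", "command", "args", "response"])
        for tr in self.log:
            w.writerow([tr.seq, f"{tr.t_min:.6f}", f"0x{tr.address:02x}",
                        tr.command, repr(tr.args), repr(tr.response)])
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Pump


@dataclass
class PumpModel:
    """Configured parameters of one peristaltic pump channel.

    ``volume_per_step_ul`` is the believed step-to-volume calibration factor
    used to convert commanded volumes into motor steps; the flow envelope is
    the achievable range at the default 1 mm inner-diameter tubing.  The
    default factor (0.5 µL/step) puts 1 CV/min on a 1 mL column (2000
    steps/min) comfortably mid-envelope.
    """

    rollers: int = PUMP_ROLLERS
    tubing_inner_diameter_mm: float = PUMP_TUBING_ID_MM
    volume_per_step_ul: float = 0.5
    flow_min_ml_min: float = PUMP_FLOW_MIN_ML_MIN
    flow_max_ml_min: float = PUMP_FLOW_MAX_ML_MIN
    noise_sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_per_step_ul <= 0:
            raise ValidationError("volume_per_step must be positive")
        if not 0 < self.flow_min_ml_min < self.flow_max_ml_min:
            raise ValidationError("flow envelope requires 0 < min < max")
        if self.noise_sd_rel < 0:
            raise ValidationError("noise sd must be non-negative")

    @property
    def volume_per_step_ml(self) -> float:
        return self.volume_per_step_ul * 1e-3


class PumpDevice(SimulatedDevice):
    """Stepper-driven peristaltic pump on the bus.

    The device owns the *actual* physics: its true µL-per-step may differ
    from the controller's believed calibration factor (``scale_error``), and
    each dispensed aliquot is multiplied by ``1 + ε`` with
    ``ε ~ Normal(0, noise_sd_rel)`` from a seeded generator.
    """

    def __init__(self, model: PumpModel, scale_error: float = 1.0) -> None:
        if scale_error <= 0:
            raise ValidationError("scale_error must be positive")
        self.model = model
        self.true_volume_per_step_ml = model.volume_per_step_ml * scale_error
        self.rng = np.random.default_rng(model.seed)
        self.total_steps = 0
        self.total_dispensed_ml = 0.0

    def advance(self, n_steps: int) -> float:
        if n_steps < 0:
            raise ValidationError("step count must be non-negative")
        nominal = n_steps * self.true_volume_per_step_ml
        if self.model.noise_sd_rel > 0 and n_steps > 0:
            eps = self.rng.normal(0.0, self.model.noise_sd_rel)
            dispensed = nominal * (1.0 + eps)
        else:
            dispensed = nominal
        self.total_steps += n_steps
        self.total_dispensed_ml += dispensed
        return dispensed

    def handle(self, command: str, args: dict) -> dict:
        if command == "advance":
            return {"dispensed_ml": self.advance(int(args["steps"]))}
        if command == "status":
            return {"total_steps": self.total_steps,
                    "total_dispensed_ml": self.total_dispensed_ml}
        raise DeviceStateError(f"pump: unknown command {command!r}")


def pump_advance(pump: PumpDevice, n_steps: int) -> float:
    """Advance the pump ``n_steps`` motor steps; return dispensed volume (mL)."""
    return pump.advance(n_steps)


# ---------------------------------------------------------------------------
# Rotary valve


class RotaryValveDevice(SimulatedDevice):
    """8-to-1 rotary selection valve with home and port position sensors."""

    UNHOMED = None

    def __init__(self, n_ports: int = ROTARY_PORTS) -> None:
        self.n_ports = n_ports
        self.current_port: Optional[int] = self.UNHOMED
        self.homed = False

    @property
    def home_sensor(self) -> bool:
        return self.homed and self.current_port == 1

    @property
    def port_sensor(self) -> bool:
        return self.current_port is not None

    def home(self) -> None:
        self.homed = True
        self.current_port = 1   # home position parks the valve at port 1

    def goto(self, port: int) -> None:
        if not self.homed:
            raise DeviceStateError("rotary valve must be homed before motion")
        if not isinstance(port, int) or isinstance(port, bool) or \
                not 1 <= port <= self.n_ports:
            raise ValidationError(f"rotary port {port} outside 1..{self.n_ports}")
        self.current_port = port

    def handle(self, command: str, args: dict) -> dict:
        if command == "home":
            self.home()
        elif command == "goto":
            self.goto(args["port"])
        elif command != "status":
            raise DeviceStateError(f"rotary: unknown command {command!r}")
        return {"port": self.current_port, "homed": self.homed,
                "port_sensor": self.port_sensor, "home_sensor": self.home_sensor}


def rotary_home(valve: RotaryValveDevice) -> RotaryValveDevice:
    valve.home()
    return valve


def rotary_goto(valve: RotaryValveDevice, port: int) -> RotaryValveDevice:
    valve.goto(port)
    return valve


# ---------------------------------------------------------------------------
# Fraction collector


@dataclass(frozen=True)
class PlateLayout:
    """Interchangeable collector top plate.

    Two shipped variants hold ten rows of small tubes (1.5 mL or 5 mL) plus
    four rows of 50 mL tubes for flow-through; every row holds one tube per
    channel.  Rows are numbered 1..10 (small) then 11..14 (large).
    """

    small_tube_ml: float = 1.5
    small_rows: int = SMALL_ROWS
    large_tube_ml: float = 50.0
    large_rows: int = LARGE_ROWS
    tubes_per_row: int = TUBES_PER_ROW

    def __post_init__(self) -> None:
        if self.small_tube_ml not in (1.5, 5.0):
            raise ValidationError("small-tube plate variants hold 1.5 or 5 mL tubes")

    @property
    def n_rows(self) -> int:
        return self.small_rows + self.large_rows

    def is_large_row(self, row: int) -> bool:
        self.validate_row(row)
        return row > self.small_rows

    def tube_capacity_ml(self, row: int) -> float:
        return self.large_tube_ml if self.is_large_row(row) else self.small_tube_ml

    def validate_row(self, row: int) -> int:
        if not isinstance(row, int) or isinstance(row, bool) or \
                not 1 <= row <= self.n_rows:
            raise ValidationError(f"row {row} outside 1..{self.n_rows}")
        return row


def default_row_positions(layout: PlateLayout, origin_steps: int = 200,
                          small_pitch: int = 400, large_pitch: int = 800) -> dict[int, int]:
    """Placeholder actuator positions for each row (strictly increasing).

    The true step geometry lives in the mechanical design, not the text; the
    defaults only preserve ordering and pitch asymmetry between tube bands.
    """
    positions: dict[int, int] = {}
    for i in range(layout.small_rows):
        positions[i + 1] = origin_steps + i * small_pitch
    base = origin_steps + layout.small_rows * small_pitch + large_pitch // 2
    for i in range(layout.large_rows):
        positions[layout.small_rows + i + 1] = base + i * large_pitch
    return positions


class ActuatorDevice(SimulatedDevice):
    """Linear actuator carrying the fraction-collector carriage."""

    def __init__(self, row_positions: dict[int, int],
                 travel_min: int = 0, travel_max: int = 10_000) -> None:
        rows = sorted(row_positions)
        steps = [row_positions[r] for r in rows]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValidationError("row positions must be strictly increasing")
        if steps and not (travel_min <= steps[0] and steps[-1] <= travel_max):
            raise ValidationError("row positions outside actuator travel limits")
        self.row_positions = dict(row_positions)
        self.travel_min = travel_min
        self.travel_max = travel_max
        self.position_steps = travel_min
        self.current_row: Optional[int] = None

    def goto_row(self, row: int) -> int:
        if row not in self.row_positions:
            raise ValidationError(f"unknown collector row {row}")
        target = self.row_positions[row]
        if not self.travel_min <= target <= self.travel_max:
            raise DeviceStateError(f"row {row} position outside travel limits")
        self.position_steps = target
        self.current_row = row
        return self.position_steps

    def handle(self, command: str, args: dict) -> dict:
        if command == "goto_row":
            self.goto_row(args["row"])
        elif command != "status":
            raise DeviceStateError(f"actuator: unknown command {command!r}")
        return {"position_steps": self.position_steps, "row": self.current_row}


def actuator_goto(actuator: ActuatorDevice, row: int) -> ActuatorDevice:
    actuator.goto_row(row)
    return actuator


# ---------------------------------------------------------------------------
# Relay board


class RelayBoardDevice(SimulatedDevice):
    """Stackable 8-channel relay driver board (drives solenoid valves)."""

    N_RELAYS = 8

    def __init__(self) -> None:
        self.states = [False] * self.N_RELAYS

    def set_relay(self, index: int, on: bool) -> None:
        if not 0 <= index < self.N_RELAYS:
            raise ValidationError(f"relay index {index} outside 0..{self.N_RELAYS - 1}")
        self.states[index] = bool(on)

    def handle(self, command: str, args: dict) -> dict:
        if command == "set":
            self.set_relay(int(args["relay"]), bool(args["on"]))
        elif command != "status":
            raise DeviceStateError(f"relay board: unknown command {command!r}")
        return {"states": list(self.states)}
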
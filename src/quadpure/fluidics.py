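"""Fluidic flow-path topology for the four-channel purifier.

The instrument plumbs up to eight shared buffer bottles through a motorized
8-to-1 rotary selection valve and a 1-to-4 splitter into four independent
column channels.  Each channel carries three 2/3-way solenoid valves:

* ``INPUT_SELECT``   — choose between the shared buffer line and the
  channel's dedicated load (sample) input;
* ``PRE_COLUMN_PURGE`` — divert the pre-column path to waste (used when
  flushing lines or loading new reagents);
* ``POST_COLUMN_SELECT`` — send column effluent to waste or to the
  fraction collector.

A 6-roller peristaltic pump sits between the input-select valve and the
purge valve; a passive back-pressure regulator sits after the column.

Valve polarity (documented assumption, chosen so that a power loss parks
flow at waste):

=====================  ==============  ============
role                   de-energized    energized
=====================  ==============  ============
INPUT_SELECT           buffer          load
PRE_COLUMN_PURGE       to column       to waste
POST_COLUMN_SELECT     to waste        to collector
=====================  ==============  ============

The topology is held in a :class:`networkx.DiGraph`; route resolution walks
the graph following the edge selected by each valve's state, so the routing
logic and the drawn flow-path diagram are the same object.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import RoutingError, ValidationError

N_BUFFER_PORTS = 8       # 8-to-1 rotary selection valve
MAX_CHANNELS = 4         # front panel carries exactly four pump/valve sets
VALVES_PER_CHANNEL = 3   # three 2/3-way solenoid valves per channel


class SolenoidRole(enum.Enum):
    INPUT_SELECT = "input_select"
    PRE_COLUMN_PURGE = "pre_column_purge"
    POST_COLUMN_SELECT = "post_column_select"


class SourceKind(enum.Enum):
    BUFFER = "buffer"
    LOAD = "load"


class FlowSink(enum.Enum):
    PRE_COLUMN_WASTE = "pre_column_waste"
    POST_COLUMN_WASTE = "post_column_waste"
    FRACTION_COLLECTOR = "fraction_collector"


def validate_buffer_port(port: int, n_ports: int = N_BUFFER_PORTS) -> int:
    if not isinstance(port, int) or isinstance(port, bool):
        raise ValidationError(f"buffer port must be an integer, got {port!r}")
    if not 1 <= port <= n_ports:
        raise ValidationError(f"buffer port {port} outside 1..{n_ports}")
    return port


def validate_channel(channel: int, n_channels: int = MAX_CHANNELS) -> int:
    if not isinstance(channel, int) or isinstance(channel, bool):
        raise ValidationError(f"channel must be an integer, got {channel!r}")
    if not 1 <= channel <= n_channels:
        raise ValidationError(f"channel {channel} outside 1..{n_channels}")
    return channel


@dataclass(frozen=True)
class SolenoidState:
    """State of one 2/3-way solenoid valve."""

    role: SolenoidRole
    energized: bool = False


@dataclass(frozen=True)
class FlowSource:
    """A flow origin: a shared buffer port, or a channel-private load input."""

    kind: SourceKind
    buffer_port: Optional[int] = None   # required iff kind == BUFFER
    channel: Optional[int] = None       # required iff kind == LOAD

    def __post_init__(self):
        if self.kind is SourceKind.BUFFER:
            if self.buffer_port is None:
                raise ValidationError("BUFFER source requires a buffer_port")
            validate_buffer_port(self.buffer_port)
            if self.channel is not None:
                raise ValidationError("BUFFER sources are shared; no channel")
        else:
            if self.channel is None:
                raise ValidationError("LOAD source requires a channel")
            validate_channel(self.channel)
            if self.buffer_port is not None:
                raise ValidationError("LOAD sources have no buffer port")

    @classmethod
    def buffer(cls, port: int) -> "FlowSource":
        return cls(SourceKind.BUFFER, buffer_port=port)

    @classmethod
    def load(cls, channel: int) -> "FlowSource":
        return cls(SourceKind.LOAD, channel=channel)

    @property
    def label(self) -> str:
        if self.kind is SourceKind.BUFFER:
            return f"buffer:{self.buffer_port}"
        return f"load:ch{self.channel}"


@dataclass(frozen=True)
class RouteState:
    """The resolved route of one channel: which source feeds which sink."""

    channel: int
    source: FlowSource
    sink: FlowSink


@dataclass
class FluidicGraph:
    """Directed flow network: shared rotary + splitter, per-channel chains."""

    graph: nx.DiGraph
    n_channels: int
    n_buffer_ports: int

    def node_kinds(self) -> Mapping[str, int]:
        """Count nodes by their ``kind`` attribute."""
        counts: dict[str, int] = {}
        for _, data in self.graph.nodes(data=True):
            counts[data["kind"]] = counts.get(data["kind"], 0) + 1
        return counts

    def channel_chain(self, channel: int) -> list[str]:
        """Ordered node names of one channel's main chain (valve→…→valves)."""
        validate_channel(channel, self.n_channels)
        return [
            f"input_valve:{channel}",
            f"pump:{channel}",
            f"purge_valve:{channel}",
            f"column:{channel}",
            f"bpr:{channel}",
            f"post_valve:{channel}",
        ]


def build_graph(n_channels: int = MAX_CHANNELS,
                n_buffer_ports: int = N_BUFFER_PORTS) -> FluidicGraph:
    """Build the flow-path network for a rig with the given geometry.

    The shared section is ``buffer ports -> rotary -> splitter``; each channel
    chain is ``input valve -> pump -> purge valve -> column -> back-pressure
    regulator -> post-column valve -> {waste, collector}``, with the purge
    valve offering an early exit to pre-column waste.

    Raises
    ------
    ValidationError
        For 0 channels, more than four channels, or more than eight buffer
        ports (the front panel holds exactly four pump/valve sets and the
        rotary valve has eight inlet ports).
    """
    if not 1 <= n_channels <= MAX_CHANNELS:
        raise ValidationError(
            f"rig must declare 1..{MAX_CHANNELS} channels, got {n_channels}")
    if not 1 <= n_buffer_ports <= N_BUFFER_PORTS:
        raise ValidationError(
            f"rig must declare 1..{N_BUFFER_PORTS} buffer ports, "
            f"got {n_buffer_ports}")

    g = nx.DiGraph()
    g.add_node("rotary", kind="rotary")
    g.add_node("splitter", kind="splitter")
    g.add_edge("rotary", "splitter")
    for p in range(1, n_buffer_ports + 1):
        g.add_node(f"buffer:{p}", kind="buffer_port", port=p)
        g.add_edge(f"buffer:{p}", "rotary", port=p)

    for ch in range(1, n_channels + 1):
        g.add_node(f"load:{ch}", kind="load", channel=ch)
        g.add_node(f"input_valve:{ch}", kind="solenoid", channel=ch,
                   role=SolenoidRole.INPUT_SELECT)
        g.add_node(f"pump:{ch}", kind="pump", channel=ch)
        g.add_node(f"purge_valve:{ch}", kind="solenoid", channel=ch,
                   role=SolenoidRole.PRE_COLUMN_PURGE)
        g.add_node(f"column:{ch}", kind="column", channel=ch)
        g.add_node(f"bpr:{ch}", kind="back_pressure_regulator", channel=ch)
        g.add_node(f"post_valve:{ch}", kind="solenoid", channel=ch,
                   role=SolenoidRole.POST_COLUMN_SELECT)
        g.add_node(f"pre_waste:{ch}", kind="sink", channel=ch,
                   sink=FlowSink.PRE_COLUMN_WASTE)
        g.add_node(f"post_waste:{ch}", kind="sink", channel=ch,
                   sink=FlowSink.POST_COLUMN_WASTE)
        g.add_node(f"collector:{ch}", kind="sink", channel=ch,
                   sink=FlowSink.FRACTION_COLLECTOR)

        # input-select valve: de-energized = buffer, energized = load
        g.add_edge("splitter", f"input_valve:{ch}", selected_when=False)
        g.add_edge(f"load:{ch}", f"input_valve:{ch}", selected_when=True)
        g.add_edge(f"input_valve:{ch}", f"pump:{ch}")
        g.add_edge(f"pump:{ch}", f"purge_valve:{ch}")
        # purge valve: de-energized = to column, energized = to waste
        g.add_edge(f"purge_valve:{ch}", f"column:{ch}", selected_when=False)
        g.add_edge(f"purge_valve:{ch}", f"pre_waste:{ch}", selected_when=True)
        g.add_edge(f"column:{ch}", f"bpr:{ch}")
        g.add_edge(f"bpr:{ch}", f"post_valve:{ch}")
        # post-column valve: de-energized = waste, energized = collector
        g.add_edge(f"post_valve:{ch}", f"post_waste:{ch}", selected_when=False)
        g.add_edge(f"post_valve:{ch}", f"collector:{ch}", selected_when=True)

    return FluidicGraph(graph=g, n_channels=n_channels,
                        n_buffer_ports=n_buffer_ports)


_DEFAULT_GRAPH: Optional[FluidicGraph] = None


def _default_graph() -> FluidicGraph:
    global _DEFAULT_GRAPH
    if _DEFAULT_GRAPH is None:
        _DEFAULT_GRAPH = build_graph()
    return _DEFAULT_GRAPH


def _valve_map(valves: Iterable[SolenoidState]) -> dict[SolenoidRole, bool]:
    vmap = {v.role: v.energized for v in valves}
    missing = set(SolenoidRole) - set(vmap)
    if missing:
        raise ValidationError(
            f"incomplete valve set: missing {sorted(r.value for r in missing)}")
    return vmap


def resolve_route(rotary_port: int,
                  valves: Iterable[SolenoidState],
                  channel: int,
                  fluidics: Optional[FluidicGraph] = None) -> RouteState:
    """Resolve which source feeds which sink for one channel.

    A total function over valid states: every combination of rotary port and
    the three solenoid states maps to exactly one :class:`RouteState`.  The
    route is found by walking the flow network from the input-select valve,
    at each valve following the edge its state selects; diversion at the
    purge valve therefore short-circuits the post-column valve.
    """
    fl = fluidics or _default_graph()
    validate_buffer_port(rotary_port, fl.n_buffer_ports)
    validate_channel(channel, fl.n_channels)
    vmap = _valve_map(valves)

    if vmap[SolenoidRole.INPUT_SELECT]:
        source = FlowSource.load(channel)
    else:
        source = FlowSource.buffer(rotary_port)

    g = fl.graph
    node = f"input_valve:{channel}"
    while g.nodes[node]["kind"] != "sink":
        succs = list(g.successors(node))
        if g.nodes[node]["kind"] == "solenoid" and any(
                "selected_when" in g.edges[node, n] for n in succs):
            # valve selects among its outgoing paths (the input-select
            # valve instead selects among its inlets, handled above)
            state = vmap[g.nodes[node]["role"]]
            succs = [n for n in succs
                     if g.edges[node, n].get("selected_when") == state]
        assert len(succs) == 1, f"non-unique continuation at {node}"
        node = succs[0]
    return RouteState(channel=channel, source=source,
                      sink=g.nodes[node]["sink"])


@dataclass(frozen=True)
class ValvePlan:
    """Solenoid states (and rotary port, for buffer sources) realizing a route."""

    channel: int
    valves: tuple[SolenoidState, SolenoidState, SolenoidState]
    rotary_port: Optional[int]   # None when the source is a load input


def valve_plan(source: FlowSource, sink: FlowSink, channel: int,
               fluidics: Optional[FluidicGraph] = None) -> ValvePlan:
    """Invert :func:`resolve_route`: find valve states realizing (source, sink).

    Round-trip property: ``resolve_route(*valve_plan(s, k, ch))`` returns
    ``(s, k)`` for every reachable pair.

    Raises
    ------
    RoutingError
        For unreachable pairs — a load input belonging to a different
        channel (channels are fluidically independent downstream of the
        splitter), or a pre-column-waste sink requested with full column
        routing that cannot bypass it.
    """
    fl = fluidics or _default_graph()
    validate_channel(channel, fl.n_channels)
    if source.kind is SourceKind.LOAD and source.channel != channel:
        raise RoutingError(
            f"load input of channel {source.channel} cannot reach a sink on "
            f"channel {channel}")
    if source.kind is SourceKind.BUFFER:
        validate_buffer_port(source.buffer_port, fl.n_buffer_ports)

    input_state = source.kind is SourceKind.LOAD
    purge_state = sink is FlowSink.PRE_COLUMN_WASTE
    # post-column valve is parked at waste whenever flow never reaches it
    post_state = sink is FlowSink.FRACTION_COLLECTOR

    plan = ValvePlan(
        channel=channel,
        valves=(
            SolenoidState(SolenoidRole.INPUT_SELECT, input_state),
            SolenoidState(SolenoidRole.PRE_COLUMN_PURGE, purge_state),
            SolenoidState(SolenoidRole.POST_COLUMN_SELECT, post_state),
        ),
        rotary_port=source.buffer_port
        if source.kind is SourceKind.BUFFER else None,
    )
    return plan
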
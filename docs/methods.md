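# Methods

## What is modelled

`quadpure` models the control surface of a four-channel affinity
chromatography instrument: which source feeds which sink on each channel,
how many motor steps a commanded volume becomes, where every dispensed
millilitre lands, and how a client drives all of that over a network
socket. It deliberately does **not** model chromatography itself: there is
no binding/breakthrough chemistry, no gradient elution, no UV/A280 trace,
and no pressure–flow physics (the back-pressure regulators are inert graph
nodes). A fraction's "composition" is the mobile phase routed into it, not
its protein content.

## Fluidic topology

The flow network is a directed graph: eight buffer inlets → rotary valve →
1-to-4 splitter, then per channel input-select valve → pump → purge valve →
column → back-pressure regulator → post-column valve → {pre-column waste,
post-column waste, fraction collector}. Route resolution walks this graph
following the edge each valve's state selects, which makes it total by
construction: all 8 ports × 8 valve combinations × 4 channels resolve to
exactly one (source, sink), and the purge valve dominates the post-column
valve because flow diverted to pre-column waste never reaches it. The unit
tests check the walk against an independent hand-written boolean truth
table, exhaustively.

Valve polarity is not a physical datum we have, so it is a documented
package assumption: de-energized = buffer-select / to-column / to-waste,
chosen so that a power loss parks every channel's effluent at waste. The
`valve_plan` inverse parks the post-column valve at waste whenever the sink
is upstream of it.

Because the rotary valve and splitter are shared, a buffer-port change
while another channel is engaged on a different port would silently switch
that channel's feed. The controller refuses such requests with a
shared-buffer conflict error; a channel releases its claim when it is
parked (all valves de-energized) or re-routed. Lockstep protocol execution
makes the conflict unreachable during a run — every flowing channel uses
the same buffer step — but the interlock protects interactive use. Whether
the physical instrument interlocks this case is unknown; the error-first
policy is this package's choice.

## Virtual hardware

Every peripheral is a device object registered at a 7-bit address (≤128) on
a simulated bus; all actuation flows through logged bus transactions, so
the controller is indifferent to what implements the bus (the driver
substitutability test swaps in a wrapped bus). Time is a virtual clock
advanced by volume/rate — parallel dispenses advance it once by the longest
duration — so a 128-minute purification executes in well under a second.

The pump converts commanded volume to steps with a believed calibration
factor (`volume_per_step`, default 0.5 µL/step, chosen so 1 CV/min on a
1 mL column ≈ 33 steps/s sits mid-envelope between the 4×10⁻⁶ and
21 mL/min flow limits at 1 mm tubing; the true motor step geometry is not
public, only the flow envelope is). The simulated device owns the *actual*
physics: an optional per-channel scale error (truth unknown to the
controller, used to exercise calibration) and a synthetic noise model —
each dispensed aliquot is multiplied by 1 + ε, ε ~ N(0, sd), seeded. The
default synthetic sd is 1 % per aliquot. This noise is an intentionally
crude stand-in for tubing elasticity and hydrostatic-head effects: it is
aliquot-wise (independent of aliquot volume), unbiased, and Gaussian,
none of which is guaranteed of a real pump. Passing the consistency tests
therefore shows the control/ledger arithmetic is right under this noise
model, not that real hardware meets those numbers.

Collector row positions in actuator steps are config-defined placeholders
(strictly increasing, small-row band then large-row band); the real
geometry lives in the mechanical design. A tube that would overfill keeps
its contents at capacity and diverts the excess to a ledgered "spill"
quantity with a flag — never a silent truncation — so conservation checks
still close.

## Protocol engine

Protocols are ordered steps (equilibrate / load / wash / elute / purge /
hold) denominated in CV at a default 1 CV/min. Compilation multiplies by
each channel's column volume, assigns collector rows (elution fractions to
small rows in order, captured flow-through to large rows), expands elution
into per-fraction dispense + carriage moves (fraction count =
⌈volume/size⌉), and rejects at compile time: undefined buffer ports, more
fractions than free rows, and compiled rates above the pump ceiling.

Execution dispenses in quanta of `tick_cv` (default 0.5 CV) per channel
with a control point between quanta. Pause stops at a quantum boundary and
resume completes the remaining volume exactly (remaining volume is
bookkept, not recomputed), hold lets the current step finish and then
idles awaiting resume, abort stops pumps and parks all valves at waste with
the ledger preserved. The quantum is a simulation granularity choice: small
enough that pause/abort land "mid-step", large enough that a full
purification is a few hundred bus transactions.

Elution tubes may carry an operator-loaded neutralizer prefill (e.g.
0.15 CV of 1 M Tris pH 9.0 for low-pH Protein A elution); the ledger
records it but the machine never dispenses it, and capacity checks use
dispensed + prefill. Load flow-through capture into the 50 mL rows is
per-protocol: the 1 mL IMAC protocol captures its 50 mL flow-through; the
5 mL variant's 1 L load cannot fit a 50 mL tube and is routed to waste
(the ledger still audits the full load volume by source).

The engine keeps one cumulative session ledger and persistent row cursors,
so a protocol executed step-by-step through client wrappers allocates the
same rows and produces the same ledger as the compiled protocol executed
in one call — the equivalence the client tests assert.

## Calibration

`calibrate_flow` commands `target_rate × CV × window` per timed window and
rescales the believed factor by measured/target (the measured volume is the
simulation's delivered volume — the desk-scale analogue of weighing the
dispense). A correctly calibrated pump is a fixed point; a mis-scaled pump
is corrected exactly in one pass when noiseless, to within step-rounding
otherwise. The measurement averages 5 one-minute windows by default so
that, under 1 % aliquot noise, the calibration bias (≈0.45 % sd) stays
well below the per-dispense spread; the fraction-consistency experiment
(30 one-minute single-aliquot dispenses × 4 channels after one coarse
parallel calibration, pumps starting within ±5 % of true scale) then shows
a grand-mean fraction volume within 1 % of 1 CV with ≈1 % spread.

## Client–server protocol

The wire format is original to this package (the concept — availability
broadcast, single client, configuration-on-connect, dual acknowledgement —
is the instrument's; its concrete grammar and ports are not public):
newline-delimited JSON over TCP, JSON datagrams over UDP for the idle
broadcast (default every 1 s; the broadcast address defaults to 127.0.0.1
for desk-scale use and is configurable for a real subnet). Every REQUEST
gets exactly one ACK then one terminal COMPLETE/ERROR with the same
client-assigned id; unknown commands and bad arguments are still ACKed
first, then errored. Commands execute serially; the one deliberate
exception is that a long-running protocol command streams STATUS progress
between its ACK and terminal and services nested run-control requests
(pause / resume / hold / abort / status) arriving on the same connection,
since an operator must be able to pause a run the server is currently
executing. A client disconnect — graceful or forced — aborts any run,
resets the controller (configuration dropped, valves safe), and frees the
lock.

## Shipped definitions

Rig configs `histrap_1ml` / `histrap_5ml` / `protein_a_1ml` (four columns
of 1/5/1 mL; 1.5, 5 and 1.5 mL small-tube plates) pair with the protocols
of the same names: IMAC 10 CV equilibrate, 50 CV (1 mL) or 200 CV (5 mL)
load, 60 CV wash, eight 1 CV fractions; Protein A 10 CV equilibrate, 10 CV
load, 30 CV wash, five 0.85 CV fractions with 0.15 CV prefill. All shipped
configs are noiseless and perfectly scaled, so the acceptance runs are
exact; noise and scale errors are opt-in per config or via the experiment
helpers.

## Problem sizes and determinism

Tests and the acceptance script run the full shipped protocols (128 CV per
channel, four channels) — at 0.5 CV quanta that is a few hundred simulated
dispenses per run, fractions of a second of wall time, so nothing is scaled
down. All randomness (pump noise, scale errors, interleaving choices) flows
from explicit seeds; identical seeds give identical transaction logs,
ledgers, and experiment statistics.

## Known limitations

* No chemistry, pressure, or detector models (see above); flow reduction
  under rising back-pressure is representable only as a per-channel scale
  error, not a dynamic effect.
* Serial (multi-column) plumbing and gradient elution are out of scope.
* The GUI of the physical instrument is replaced by the CLI and the
  scripting wrappers; no graphical front-end ships.
* Single-client locking is advisory at the protocol level (no
  authentication or transport security).
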
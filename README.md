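# quadpure

A complete control stack for a four-channel, milligram-scale automated
protein purification instrument — fluidic routing, device drivers, hardware
controller, protocol engine, and client–server interface — running against a
fully simulated hardware backend, so purification protocols can be compiled,
executed, and audited entirely at the desk.

## The instrument and who this is for

Parallel affinity chromatography lets a protein-production lab purify up to
four proteins at once, each on its own single-use column (IMAC for
His-tagged antigens, Protein A for antibodies). The instrument this package
controls has:

* a shared, motorized **8-to-1 rotary valve** feeding all channels one of
  eight buffers through a 1-to-4 splitter;
* per channel, **three 2/3-way solenoid valves** (buffer/load input select,
  pre-column purge to waste, post-column waste/collector select), a
  **6-roller peristaltic pump** (4×10⁻⁶–21 mL/min at 1 mm tubing) between
  the input-select and purge valves, the column, and a passive back-pressure
  regulator;
* an automated **fraction collector** on a linear actuator: ten rows of
  small tubes (1.5 or 5 mL variants) plus four rows of 50 mL tubes for
  flow-through, one tube per channel per row;
* every peripheral on one **I2C bus** (up to 128 addresses), driven by a
  single-board computer running an always-on command server.

`quadpure` re-creates that stack in Python with the hardware replaced by a
simulated bus and a virtual clock, so control logic, protocols, run
auditing, and the network protocol can be developed and tested without an
instrument. Intended users: instrument-software developers, and protein
scientists who want to dry-run or script a purification before committing
sample.

## The core abstractions

* **Protocols are CV-denominated.** Step volumes and rates are written in
  column volumes (CV) and CV/min; the engine multiplies by each channel's
  configured column volume at compile time, so one protocol file serves
  1 mL and 5 mL columns. All channels advance in lockstep (one shared
  rotary valve makes buffer steps inherently global); load steps are
  channel-private and support per-channel volume overrides.
* **Every millilitre is ledgered.** A run produces a `RunLedger` with one
  record per collected fraction (volume, operator prefill, source
  composition), waste totals per sink and per source, pumped totals, and a
  simulated-time event log. Noiseless runs conserve volume exactly:
  `pumped = Σ fractions + Σ waste`.
* **Calibration is gravimetric.** `volume_per_step' = volume_per_step ×
  (measured / target)` over a few timed dispense windows; a mis-scaled pump
  is corrected in one pass.
* **One client at a time.** The server broadcasts availability on UDP while
  idle; a TCP client takes an exclusive lock, selects a named hardware
  configuration, and every request is answered by an ACK (receipt) then a
  COMPLETE or ERROR (outcome), with progress streamed and pause / hold /
  resume / abort honoured mid-run.

## Worked example

Run the shipped His-tag IMAC protocol (10 CV equilibration, 50 CV load with
flow-through capture, 60 CV wash, eight 1 CV elution fractions, all at
1 CV/min) on the noiseless simulator, one channel:

```bash
quadpure run histrap_1ml --channels 2 --report-dir reports
```

prints

```
channel 2: pumped 128.000 mL, waste 70.000 mL, 8 elution fraction(s)
  row 11 flow-through: 50.000 mL (+0.000 mL prefill)
  row  1 fraction 1: 1.000 mL (+0.000 mL prefill)
  ...
  row  8 fraction 8: 1.000 mL (+0.000 mL prefill)
reports written to reports/
```

Reading: the channel pumped 128 mL = 128 CV in 128 simulated minutes (10
equilibration + 50 load + 60 wash + 8 elution); the 70 mL waste is the
equilibration and wash effluent; the 50 mL load flow-through landed in the
first 50 mL row (row 11); elution was cut into exactly eight 1.000 mL
fractions in small-tube rows 1–8. `reports/ledger.csv` holds the same
numbers row by row with each fraction's source composition.

The same run, scripted:

```python
from quadpure import PurifierServer, ClientSession

with PurifierServer(status_port=0) as server:
    with ClientSession(server.host, server.command_port) as session:
        session.select_config("protein_a_1ml")
        session.equilibrate(buffer_port=1, volume_cv=10)
        session.load(volume_cv=10, collect_flowthrough=True)
        session.wash(buffer_port=1, volume_cv=30)
        ledger = session.elute(buffer_port=2, volume_cv=4.25,
                               fraction_size_cv=0.85, prefill_cv=0.15)
print(ledger.summary())
```

which ends with five 0.850 mL fractions per channel, each ledgered on top of
a 0.150 mL operator-loaded Tris prefill (the low-pH antibody elution is
neutralized in the tube).

## Layout

```
src/quadpure/
  fluidics.py     flow-path graph, route resolution, valve planning
  virtual.py      simulated I2C bus, pumps, rotary valve, collector
  control.py      named rig configurations + hardware controller
  protocol.py     protocol compiler/engine, run ledger, calibration
  server.py       TCP command server + UDP availability broadcast
  client.py       session middleware, command wrappers, file runner
  experiments.py  calibration-recovery and fraction-consistency studies
  cli.py          quadpure serve/discover/configs/protocols/run/...
  configs/        shipped rig configurations (YAML)
  protocols/      shipped purification protocols (YAML)
docs/methods.md   model assumptions, defaults, numerical choices
```
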
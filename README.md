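# perfusim

A hardware-free simulator of automated stimulation/perfusion
electrophysiology experiments — the kind run on brain slices (LTP/LTD with
field-potential recording) and on voltage-clamped single cells
(agonist/antagonist concentration–response with fast solution exchange).

In such experiments a data-acquisition host executes a *protocol script*:
an ordered list of stimulation **Sweep** events (P0/P1 single-pulse,
T0/T1 train), **Loop** and **Delay** events for timing, and **Perfuse**
events that switch the solution bathing the preparation by driving a
perfusion valve controller. `perfusim` implements that whole engine with
the hardware replaced by a virtual rig, so protocol logic, valve
sequencing, solution-transport consequences and on-line analysis can be
developed, taught and tested at a desk.

## What is modeled

* **Protocol scripting** — a line-oriented `.proto` dialect with
  `MainProtocol`/`EndProtocol`, counted and *continuous* loops (count
  99999 = "loop until the operator unchecks it"), `RunOnce` blocks,
  solution labels and protocol linking (`[link]` block with autostart).
* **Valve controllers** — analog (1 V/channel for 8-channel units,
  0.5 V/channel for 16-channel units), 4-bit binary (8/15/16-channel
  conventions) and bit-per-valve digital output; switch plans for
  *standard* (close old + open new simultaneously), *pre-flush* (flush the
  incoming line to waste first), *continuous-flow-to-waste* (three-way
  NO/NC valves) and *stepper* (1 V per tube position) perfusion.
* **Within-sweep perfusion** — sweeps carry three command epochs whose
  amplitude selects a channel in channel-number units; the sentinel −1
  holds whatever channel the last Fast Perfuse event selected.
* **The virtual rig** — plug-flow transport (the stale dead volume of a
  switched-on line arrives first, over volume/flow seconds, into a
  well-mixed chamber) and parameterized response synthesis: stereotyped
  fEPSPs whose initial slope is the pathway slope, with a train-induced
  potentiation `ltp_factor` blocked when an inhibitor solution is in the
  chamber; Hill/Schild agonist currents
  `Emax·cʰ/(cʰ + (EC50·(1+B/Ki))ʰ)`; RC seal-test transients.
* **On-line measurements** — OLS slope, maximum sliding-window slope, peak
  amplitude, population-spike amplitude (trough-to-chord), average
  amplitude, area, 10–90 % rise time, decay time, half-amplitude duration,
  input resistance, and series resistance by single/double exponential
  transient fitting.

Useful design arithmetic is included: dead volume of a tubing segment,
solutions required for an agonist/antagonist design (`n_ag + n_antag` when
the antagonist stays bound, `n_antag + n_ag·n_antag` when it is
displaced), and the solution capacity of multi-line stepper rigs.

## Worked example

```sh
perfusim examples examples/     # write the bundled protocols and rigs
perfusim run examples/slice_ltp_perfusion.proto \
    --rig examples/slice_rig.yaml \
    --controls examples/slice_ltp_controls.csv --out out/
```

prints

```
32 sweeps, 2 distinct solutions, end t=960.3s -> out/
```

This is a sequential slice LTP experiment: the script starts perfusing
Ch1 (ACSF), runs a baseline loop of single-pulse P0 sweeps every 30 s
until the simulated operator unchecks it (after sweep 3, per the controls
file), switches to Ch2 (a CaMKII inhibitor), delivers a 100-pulse T0
induction train, washes back to Ch1 and delivers a second train.  The
virtual slice shows no potentiation after the first train (inhibitor in
the chamber above the blocking threshold) and a 1.5× slope increase after
the second — visible in `out/spreadsheet.csv`, with the valve actions in
`out/timeline.csv` and the labeled perfusion changes in
`out/experiment.log`:

```
0:00:00  Perfuse Slow0 Ch1 'ACSF'
0:00:00  P0sweep
...
0:01:30  Perfuse Slow0 Ch2 'CaMKII Inhibitor'
```

The same engine runs linked fast-perfusion patch-clamp protocols:

```sh
perfusim link examples/fast_perfusion1.proto examples/fast_perfusion2.proto \
    examples/fast_perfusion3.proto --rig examples/patch_rig_16ch.yaml --out out2/
# -> 3 protocols, 36 sweeps, 15 distinct solutions -> out2/
```

Each protocol continuously perfuses one antagonist channel and applies
four agonist+antagonist channels for 1 s inside its sweeps; three linked
protocols cover 3 antagonist + 12 combination solutions = 15 in total.

The library mirrors the CLI: `parse_protocol`, `run_protocol`,
`run_linked`, `render_sweep`, `plan_preflush_switch`, `advance_transport`,
`measure_slope`, `series_resistance_fit`, … — see the module docstrings
under `src/perfusim/`.

## Layout

```
src/perfusim/
  protocol_model.py   # .proto dialect: parse / validate / serialize
  sweep_engine.py     # stimulus trains, command epochs -> sampled waveforms
  perfusion.py        # encodings, switch plans, design arithmetic
  executor.py         # discrete-event interpreter, linking, logging
  virtual_rig.py      # plug-flow transport + synthetic fEPSP/patch responses
  analysis.py         # per-sweep measurement battery
  rig.py              # rig configuration (YAML)
  fixtures.py         # worked example protocols and rigs
  cli.py              # perfusim run / link / validate / examples
```
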
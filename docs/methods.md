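# Methods

This note documents the models behind `perfusim`, the defaults and why
they were chosen, and what the simulator does and does not claim about
real experiments.

## Protocol execution model

The executor is a discrete-event interpreter over a simulated wall clock
in dimensionless seconds; nothing sleeps. Each sweep occupies
`[t_start, t_start + duration)` and the clock then advances by the
inter-sweep interval (default 30 s, the usual baseline stimulation rate
for slice work; start-to-start, so an interval shorter than the sweep
falls back to the sweep duration). `Delay` adds its seconds; `Perfuse`
emits the line's switch plan at the current time and then advances the
clock past the switchover (flush duration, if any, plus the valve travel
time), which is what keeps slow-line valve actions strictly *between*
sweeps. Only Fast-line sweep epochs change solutions inside a sweep.

Operator actions are simulated as control events triggered at a wall time
or after the k-th completed sweep. A continuous loop tests its uncheck at
the *end* of each iteration, so an uncheck arriving mid-sweep finishes
the sweep — matching checkbox semantics on the real instrument. A
continuous loop with no uncheck control anywhere is rejected up front
rather than spinning forever. `RunOnce` blocks run their body once per
check, consumed in script order; block indices are assigned by position
in the script, not by entry order, so a `RunOnce` inside a loop keeps one
identity across iterations.

Protocol linking concatenates scripts on one timeline: each follow-on
protocol logs a *load* entry and, if its autostart flag is set (or a
start control event fires), a *start* entry. The experimental log holds
exactly one entry per perfusion change (time, line, channel, solution
label — defaulting to `Ch<n>`), per sweep, and per link event; warnings
(e.g. a manual Apply without Override) are kept separately so the log
remains a faithful event record.

Determinism: with identical script, rig, controls and seed the record is
bit-identical. The only randomness is biology noise and the optional
slow-port latency jitter (uniform, 0 by default, capped at 50 ms —
static digital ports are written by the host CPU and are only
millisecond-accurate, unlike the sweep-clocked fast outputs, which the
engine treats as exact).

## Valve sequencing

Channel 0 means "all off" in every mode. Analog encoding is
`channel × volts_per_channel` (1 V/channel for 8-channel controllers,
0.5 V/channel for 16-channel ones). Sweep-epoch amplitudes are
interpreted in *channel-number units* and converted by the controller's
volts/channel at output; this reconciles an 8-channel rig, where
"amplitude 8" and "8 V" coincide, with a 16-channel rig where channel 15
is written as 15 but emitted as 7.5 V. A config flag
(`amplitude_is_volts`) selects the literal-volts interpretation instead,
for users who think in output volts.

Pre-flush bit layout: chamber valves on bits `0..n−1`, flush valves on
the next block (`n..2n−1`), anchored by the 4-channel convention that
Ch2's flush valve is bit 5. The flush duration is a controller parameter
(default 10 s — long enough to clear a typical reservoir-to-junction
line at 2 ml/min; real rigs tune it to their geometry). Pre-flush and
standard plans end in the identical chamber-valve state and differ only
in the flush actions before the switchover.

The 4-bit binary mode exposes all three published channel conventions
(8-channel, 15-channel with a reserved 0000 off code, full 16-channel
with no off code) explicitly rather than guessing one.

## Solution transport

Transport is plug flow plus a single well-mixed chamber. On a switch,
the stale contents of the dead volume upstream of the chamber valve
arrive first, over `V_stale/Q` seconds, then fresh solution; the chamber
relaxes toward the inflow with rate `Q/V_chamber`. For a standard system
the stale volume is reservoir→manifold; for pre-flush and
continuous-flow-to-waste it is only the junction→manifold segment —
strictly smaller whenever the reservoir→junction stretch is non-empty,
but never zero. Integration uses the exact exponential update within
each constant-inflow interval, so solute mass balances to numerical
precision. Staleness is a scalar volume-fraction tag, not an O₂/CO₂/pH
chemistry model; manifold mixing, laminar dispersion and valve dead
times inside the bolus are not modeled. Fast-line (patch) perfusion is
treated as instantaneous at the cell — the manifold-to-pipette dead
volume matters for absolute latency in real rigs but not for the
protocol logic simulated here.

Default geometry: 30 cm reservoir→junction + 9 cm junction→manifold of
0.8 mm ID tubing, 2 ml/min, 1 ml chamber. The 9 cm/0.8 mm segment is the
canonical junction-to-manifold dead volume (0.05 ml); the reservoir run
and flow are typical slice-rig values.

## Synthetic biology

The response models are the simplest forms that exercise every
measurement and decision path; all parameters live in the rig config.

**Slice fEPSP.** Each stimulus pulse evokes a fixed template: a small
Gaussian fiber volley followed by a negative difference-of-exponentials
synaptic deflection (rise 0.8 ms, decay 8 ms, 2 ms synaptic delay). The
template is scaled so that the OLS slope over the standard measurement
window (0.5–2.5 ms after synaptic onset) equals the pathway slope
exactly; baseline slope defaults to −0.15 mV/ms. A sweep whose train has
≥ 10 pulses counts as induction: it multiplies the pathway gain by
`ltp_factor` (default 1.5) unless an inhibitor-channel solution occupies
at least `inhibitor_block_threshold` (default 0.5) of the chamber at
train time. This is a rule, not a plasticity model: passing tests show
the engine delivers and detects the right contingencies, not that any
biological mechanism is captured.

**Patch clamp.** Agonist responses follow a Hill function with a
competitive (Schild) antagonist shift of the apparent EC50 by
`(1 + B/Ki)`, relaxing with separate on/off time constants (20/50 ms).
Defaults: Emax 500 pA, EC50 10 µM, h 1, Ki 5 µM. The bundled
concentration ladders are 1/3/10/30 µM agonist and 0/2.5/5/10 µM
antagonist. In the tightly-bound-antagonist example the agonist channels
contain no antagonist and the model does not carry bound antagonist
across solutions — receptor-state kinetics are out of scope.

**Seal test.** A voltage step ΔV through series resistance Rs gives a
peak `ΔV/Rs` decaying with `τ = Rs·Cm` toward `ΔV/(Rs+Rin)`; an optional
second exponential (default 30 % of the transient at 5× τ) mimics
imperfect compensation. `Rs → 0` is rejected as degenerate. Defaults:
Rs 10 MΩ, Rin 100 MΩ, Cm 33 pF.

## Measurements

Definitions follow standard electrophysiology practice and are
overridable per spec: slope is OLS over the window; maximum slope is the
max over 1-sample-stride sliding OLS fits (computed by correlation with
a centered ramp, identical to per-window `polyfit`); peak is the signed
extreme deviation from the baseline-window mean; rise time 10→90 % of
peak, decay time peak→37 % (an exponential-τ convention can be selected
via `decay_fraction`), duration at 50 %; the population-spike amplitude
is the distance from the trough to the chord joining its two flanking
positive peaks. Input resistance is the steady-state ΔV/ΔI (for a
voltage-clamp seal test this is Rs+Rin; subtract the fitted Rs for the
membrane alone). Series resistance fits
`I_ss + ΣAᵢ·exp(−t/τᵢ)` (1 or 2 components) from the transient peak by
bounded nonlinear least squares seeded from a log-linear tail fit, with
τ ∈ [0.01 ms, 10× the fitted span], and back-extrapolates
`Rs = ΔV/(I_ss + ΣAᵢ)`. Flat traces and windows outside the trace raise
errors rather than returning numbers.

## Numerical and design choices

* Sample rates: 10 kHz for slice and stepper sweeps, 2 kHz for the 3 s
  patch sweeps (kinetics ≥ 20 ms), 100 kHz for seal tests (τ ≈ 0.33 ms).
  Pulse edges are *scheduled* exactly (onset + k·interval, no cumulative
  rounding) and quantized only at sampling; tests on timing use the edge
  times.
* Transport integration step 0.25 s when queried by the executor
  (chamber time constant 30 s), 0.02–0.1 s in the dedicated tests.
* The `.proto` dialect (one event per line, `#` comments, `[sweeps]`,
  `[labels]`, `[link]` sections) is this package's own text format; the
  original instrument's GUI-built binary protocols have no public file
  spec. `Run`/`ElseRun` events are parsed but rejected by validation as
  unsupported, since their semantics are not documented enough to imitate.
* A continuous loop serializes with the sentinel count 99999; on
  execution the continuous flag, not the count, governs exit.
* At protocol end all lines are switched off (channel 0) unless the
  "keep last perfusion channel" control was set, mirroring the
  instrument's checkbox.
* Problem sizes in the shipped examples (24–36 sweeps, ≤ 16 channels,
  ≤ 1300 s simulated) were chosen so a full run is a few CPU-seconds;
  the engine itself has no intrinsic size limit.

## Known limitations

No hardware I/O of any kind; no binary acquisition-file output (records
export as CSV/text). No stimulus-amplitude stepping (input–output
curves), no automated baseline-stability detection — both absent from
the modeled instrument generation as well. The biology is deliberately
caricatural: no receptor kinetics, no temperature, no electrode drift,
no chamber hydrodynamics. Passing the test suite demonstrates correct
protocol logic, valve sequencing, transport bookkeeping and measurement
arithmetic on synthetic data with known ground truth — not fidelity to
any particular preparation.
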
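"""Discrete-event interpreter running protocol scripts on the virtual rig.

The executor walks a protocol script's event list in order, maintaining a
simulated wall clock (dimensionless seconds, no real-time sleeping):

* ``Sweep`` events render their waveforms, synthesize acquisition traces if
  a biology model is configured, measure them, and advance the clock by the
  inter-sweep interval;
* ``Perfuse`` events emit the controller's switch plan at the current time
  (between sweeps — only Fast-line sweep *epochs* change solutions inside a
  sweep) and are echoed to the experimental log with their solution label;
* ``Loop`` blocks repeat: counted loops a fixed number of times, continuous
  loops until a simulated operator unchecks them (checked at the end of each
  iteration, so an uncheck never truncates a sweep);
* ``RunOnce`` blocks run once per simulated operator check.

Simulated operator actions are :class:`ControlEvent` objects triggered at a
wall time or after the k-th sweep.  Protocol linking chains scripts: each
follow-on protocol is loaded when its predecessor finishes and starts
automatically iff its autostart flag is set.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import MeasurementSpec, Trace, measure_basic, measure_slope
from .perfusion import (
    ControllerConfig,
    PerfusionLine,
    SwitchPlan,
    ValveAction,
    encode_analog,
    plan_flow_to_waste_switch,
    plan_preflush_switch,
    plan_standard_switch,
)
from .protocol_model import ProtocolScript, parse_protocol, validate_protocol
from .rig import RigConfig
from .sweep_engine import SweepDef, SweepWaveforms, render_sweep
from .virtual_rig import (
    SLOPE_WINDOW_MS,
    PatchModel,
    SliceModel,
    advance_transport,
    synth_field_sweep,
    synth_patch_sweep,
)


class ProtocolRunError(RuntimeError):
    """Raised when a script cannot be executed on the given rig."""


@dataclass
class ControlEvent:
    """One simulated operator action.

    Triggered once, at wall time ``time_s`` or as soon as ``after_sweep``
    sweeps have completed.  Actions: ``uncheck_loop``, ``check_runonce``,
    ``single_sweep``, ``set_override``, ``manual_apply``,
    ``set_ch_to_last_perfuse``, ``start_protocol``.
    """

    action: str
    time_s: float | None = None
    after_sweep: int | None = None
    loop_index: int | None = None
    runonce_index: int | None = None
    sweep_name: str | None = None
    line: PerfusionLine | None = None
    channel: int | None = None
    value: bool = True
    protocol_index: int | None = None

    def __post_init__(self) -> None:
        if self.time_s is None and self.after_sweep is None:
            raise ProtocolRunError(f"control {self.action!r} needs a trigger")
        if isinstance(self.line, str):
            self.line = PerfusionLine(self.line)

    def triggered(self, t: float, sweep_count: int) -> bool:
        if self.time_s is not None and t >= self.time_s:
            return True
        return self.after_sweep is not None and sweep_count >= self.after_sweep


def parse_controls(text: str) -> list[ControlEvent]:
    """Parse a control-event CSV: ``trigger,action,args``.

    Trigger is ``t=<seconds>`` or ``sweep=<k>``; args are ``key=value``
    pairs, e.g.::

        sweep=3,uncheck_loop,loop=0
        t=600,set_override,value=true
        t=700,manual_apply,line=Slow0,channel=3
    """
    events: list[ControlEvent] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        trig, action, args = parts[0], parts[1], parts[2:]
        kwargs: dict = {"action": action}
        key, _, value = trig.partition("=")
        if key == "t":
            kwargs["time_s"] = float(value)
        elif key == "sweep":
            kwargs["after_sweep"] = int(value)
        else:
            raise ProtocolRunError(f"bad control trigger {trig!r}")
        for arg in args:
            k, _, v = arg.partition("=")
            if k == "loop":
                kwargs["loop_index"] = int(v)
            elif k == "runonce":
                kwargs["runonce_index"] = int(v)
            elif k == "sweep_name":
                kwargs["sweep_name"] = v
            elif k == "line":
                kwargs["line"] = PerfusionLine(v)
            elif k == "channel":
                kwargs["channel"] = int(v)
            elif k == "value":
                kwargs["value"] = v.lower() in ("true", "1", "yes", "on")
            elif k == "protocol":
                kwargs["protocol_index"] = int(v)
            else:
                raise ProtocolRunError(f"bad control argument {arg!r}")
        events.append(ControlEvent(**kwargs))
    return events


@dataclass
class LogEntry:
    time_s: float
    kind: str  # perfuse | sweep | link | error
    text: str


@dataclass
class SweepRecord:
    start_time_s: float
    name: str
    waveforms: SweepWaveforms
    traces: dict[str, Trace] = field(default_factory=dict)
    measurements: dict[str, float] = field(default_factory=dict)
    protocol: str = "protocol"


@dataclass
class ExperimentRecord:
    """The executed timeline of one (possibly linked) experiment."""

    sweeps: list[SweepRecord] = field(default_factory=list)
    valve_timeline: list[tuple[PerfusionLine, ValveAction]] = field(default_factory=list)
    log: list[LogEntry] = field(default_factory=list)
    activations: list[tuple[PerfusionLine, int, float]] = field(default_factory=list)
    protocols_run: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    end_time_s: float = 0.0

    def distinct_solutions(self) -> set[tuple[PerfusionLine, int]]:
        """All (line, channel) pairs ever switched onto the preparation."""
        return {(ln, ch) for ln, ch, _ in self.activations if ch != 0}

    def sweep_names(self) -> list[str]:
        return [s.name for s in self.sweeps]

    def continuous_trace(self, line: PerfusionLine, cfg: ControllerConfig,
                         rate_hz: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
        """Gap-free analog command voltage of one line over the whole run."""
        line = PerfusionLine(line)
        n = int(np.ceil(self.end_time_s * rate_hz)) + 1
        t = np.arange(n) / rate_hz
        v = np.zeros(n)
        events = sorted((ts, ch) for ln, ch, ts in self.activations if ln == line)
        times = [e[0] for e in events]
        for i, ti in enumerate(t):
            j = bisect.bisect_right(times, ti) - 1
            v[i] = encode_analog(events[j][1], cfg) if j >= 0 else 0.0
        return t, v


class _Runner:
    """Mutable execution state shared across (linked) protocols."""

    def __init__(self, rig: RigConfig, controls: list[ControlEvent],
                 inter_sweep_interval_s: float | None, seed: int):
        self.rig = rig
        self.controls = list(controls)
        self.fired = [False] * len(self.controls)
        self.interval_s = (rig.inter_sweep_interval_s
                           if inter_sweep_interval_s is None
                           else inter_sweep_interval_s)
        self.rng = np.random.default_rng(seed)
        self.t = 0.0
        self.sweep_count = 0
        self.record = ExperimentRecord()
        self.channel_state: dict[PerfusionLine, int] = {
            ln: 0 for ln in PerfusionLine}
        self.switch_history: dict[PerfusionLine, list[tuple[float, int]]] = {
            ln: [] for ln in PerfusionLine}
        self.override = False
        self.set_ch_to_last = False
        self.unchecked: set[tuple[int, int]] = set()
        self.runonce_pending: dict[tuple[int, int], int] = {}
        self.loops_entered: set[tuple[int, int]] = set()
        # current protocol context
        self.protocol_index = 0
        self.script: ProtocolScript | None = None

    # -- control handling ---------------------------------------------------

    def process_controls(self) -> None:
        for i, ev in enumerate(self.controls):
            if self.fired[i] or not ev.triggered(self.t, self.sweep_count):
                continue
            self.fired[i] = True
            self._apply_control(ev)

    def _apply_control(self, ev: ControlEvent) -> None:
        proto = (ev.protocol_index if ev.protocol_index is not None
                 else self.protocol_index)
        if ev.action == "uncheck_loop":
            self.unchecked.add((proto, ev.loop_index or 0))
        elif ev.action == "check_runonce":
            key = (proto, ev.runonce_index or 0)
            self.runonce_pending[key] = self.runonce_pending.get(key, 0) + 1
        elif ev.action == "single_sweep":
            self._run_sweep(ev.sweep_name)
        elif ev.action == "set_override":
            self.override = ev.value
            if ev.value and ev.channel is not None and ev.line is not None:
                self._manual_switch(ev.line, ev.channel)
        elif ev.action == "manual_apply":
            if self.override:
                self._manual_switch(ev.line, ev.channel)
            else:
                self.record.warnings.append(
                    f"t={self.t:.1f}s: manual Apply during a running protocol "
                    "without Override — ignored")
        elif ev.action == "set_ch_to_last_perfuse":
            self.set_ch_to_last = ev.value
        elif ev.action == "start_protocol":
            pass  # consumed by run_linked
        else:
            raise ProtocolRunError(f"unknown control action {ev.action!r}")

    def _pending_uncheck(self, loop_key: tuple[int, int]) -> list[ControlEvent]:
        return [
            ev for i, ev in enumerate(self.controls)
            if not self.fired[i] and ev.action == "uncheck_loop"
            and ((ev.protocol_index if ev.protocol_index is not None
                  else loop_key[0]), ev.loop_index or 0) == loop_key
        ]

    # -- perfusion ----------------------------------------------------------

    def _switch_plan(self, line: PerfusionLine, channel: int) -> SwitchPlan:
        cfg = self.rig.controller(line)
        if cfg is None:
            raise ProtocolRunError(f"no controller configured for {line.value}")
        tm = self.rig.transport.get(line)
        system = tm.system if tm is not None else "standard"
        from_ch = self.channel_state[line]
        if system == "preflush":
            return plan_preflush_switch(from_ch, channel,
                                        cfg.flush_duration_s, cfg)
        if system == "flow_to_waste":
            return plan_flow_to_waste_switch(from_ch, channel, cfg)
        return plan_standard_switch(from_ch, channel, cfg)

    def _emit_switch(self, line: PerfusionLine, channel: int) -> float:
        """Emit the switch plan at the current time; returns the switchover
        completion time (after any pre-flush and the valve travel time)."""
        plan = self._switch_plan(line, channel)
        cfg = self.rig.controller(line)
        t0 = self.t
        if not line.is_fast and self.rig.slow_latency_jitter_ms > 0:
            t0 += self.rng.uniform(0, self.rig.slow_latency_jitter_ms) / 1000.0
        for action in plan.shifted(t0):
            self.record.valve_timeline.append((line, action))
        t_switch = t0 + plan.duration_s
        self.channel_state[line] = channel
        self.switch_history[line].append((t_switch, channel))
        self.record.activations.append((line, channel, t_switch))
        settle = cfg.valve_switch_time_ms / 1000.0 if cfg else 0.0
        return t_switch + settle

    def _manual_switch(self, line: PerfusionLine, channel: int) -> None:
        self._emit_switch(line, channel)

    def _perfuse(self, line: PerfusionLine, channel: int) -> None:
        label = self.script.label(line, channel) if self.script else f"Ch{channel}"
        suffix = ""
        if self.override:
            suffix = " (suppressed by Override)"
        self.record.log.append(LogEntry(
            self.t, "perfuse",
            f"Perfuse {line.value} Ch{channel} '{label}'{suffix}"))
        if not self.override:
            # the next event waits for the switchover (and flush) to finish,
            # keeping slow-line valve actions strictly between sweeps
            self.t = max(self.t, self._emit_switch(line, channel))

    def chamber_concentration(self, line: PerfusionLine,
                              channels: frozenset[int], t: float) -> float:
        """Summed chamber volume-fraction of the given channels' solutions."""
        tm = self.rig.transport.get(line)
        history = self.switch_history[line]
        if tm is None or not history:
            # no hydraulic model: treat switches as instantaneous
            current = 0
            for ts, ch in history:
                if ts <= t:
                    current = ch
            return 1.0 if current in channels else 0.0
        series = advance_transport(tm, history, dt_s=0.25, t_end_s=t + 1.0)
        return sum(series.at(ch, t) for ch in channels)

    # -- sweeps -------------------------------------------------------------

    def _sweep_def(self, name: str) -> SweepDef:
        if self.script and name in self.script.sweep_defs:
            return self.script.sweep_defs[name]
        try:
            return self.rig.sweep_defs[name]
        except KeyError:
            raise ProtocolRunError(f"sweep {name!r} not defined on rig or script")

    def _run_sweep(self, name: str) -> None:
        sweep = self._sweep_def(name)
        ic1_cfg = self.rig.controller(self.rig.ic1_line) or ControllerConfig(
            line=self.rig.ic1_line, mode="analog", n_channels=16)
        current_ch = self.channel_state[self.rig.ic1_line]
        wf = render_sweep(sweep, current_ch, ic1_cfg)
        t_start = self.t
        self.record.log.append(LogEntry(t_start, "sweep", name))

        # within-sweep perfusion epochs (Fast line only)
        spans = sweep.epoch_channels(current_ch)
        prev_ch = current_ch
        for (start_ms, end_ms, ch), epoch in zip(spans, sweep.ic1_epochs or ()):
            if ch != prev_ch:
                self.record.valve_timeline.append((
                    self.rig.ic1_line,
                    ValveAction(t_start + start_ms / 1000.0, "AnalogOut1",
                                None, encode_analog(ch, ic1_cfg))))
            if epoch.amplitude != -1.0 and ch != 0:
                self.record.activations.append(
                    (self.rig.ic1_line, ch, t_start + start_ms / 1000.0))
            prev_ch = ch
        if spans and prev_ch != current_ch:
            self.record.valve_timeline.append((
                self.rig.ic1_line,
                ValveAction(t_start + spans[-1][1] / 1000.0, "AnalogOut1",
                            None, encode_analog(current_ch, ic1_cfg))))

        traces: dict[str, Trace] = {}
        measurements: dict[str, float] = {}
        bio = self.rig.biology
        if isinstance(bio, SliceModel) and sweep.s0_train is not None:
            is_train = sweep.s0_train.pulse_count >= bio.train_pulse_threshold
            inhib = 0.0
            if is_train:
                inhib = self.chamber_concentration(
                    PerfusionLine.SLOW0, bio.inhibitor_channels, t_start)
            traces["AD0"] = synth_field_sweep(bio, sweep, inhib, "S0")
            pulse_t = sweep.s0_train.edge_times_ms()[0]
            window = (pulse_t + SLOPE_WINDOW_MS[0], pulse_t + SLOPE_WINDOW_MS[1])
            measurements["slope0"] = measure_slope(traces["AD0"], window)
        elif isinstance(bio, PatchModel) and spans:
            dt_ms = 1000.0 / sweep.sample_rate_hz
            n = sweep.n_samples
            ag = np.zeros(n)
            antag = np.zeros(n)
            sol = self.rig.channel_solution_um
            bounds = [(int(round(s / dt_ms)), int(round(e / dt_ms)), ch)
                      for s, e, ch in spans] + [
                (int(round(spans[-1][1] / dt_ms)), n, current_ch)]
            for i0, i1, ch in bounds:
                a, b = sol.get(ch, (0.0, 0.0))
                ag[i0:i1] = a
                antag[i0:i1] = b
            traces["AD0"] = synth_patch_sweep(bio, ag, antag, dt_ms)
            measurements["peak_pA"] = measure_basic(
                traces["AD0"],
                MeasurementSpec("peak_amplitude", (0.0, (n - 1) * dt_ms)))

        self.record.sweeps.append(SweepRecord(
            t_start, name, wf, traces, measurements,
            self.script.name if self.script else "protocol"))
        self.sweep_count += 1
        self.t = t_start + max(self.interval_s, sweep.duration_ms / 1000.0)

    # -- event-tree execution ----------------------------------------------

    def run_script(self, script: ProtocolScript) -> None:
        self.script = script
        self.record.protocols_run.append(script.name)
        tree, _, _ = _build_tree(script.events, 0, [0, 0])
        self._run_nodes(tree)
        self.record.end_time_s = self.t

    def _run_nodes(self, nodes) -> None:
        for node in nodes:
            self.process_controls()
            kind = node[0]
            if kind == "leaf":
                ev = node[1]
                if ev.kind == "Sweep":
                    self._run_sweep(ev.sweep_name)
                elif ev.kind == "Delay":
                    self.t += ev.delay_s
                elif ev.kind == "Perfuse":
                    self._perfuse(ev.line, ev.channel)
                else:
                    raise ProtocolRunError(f"cannot execute event {ev.kind!r}")
            elif kind == "loop":
                self._run_loop(node[1], node[2], node[3])
            elif kind == "runonce":
                key = (self.protocol_index, node[3])
                if self.runonce_pending.get(key, 0) > 0:
                    self.runonce_pending[key] -= 1
                    self._run_nodes(node[2])
            else:  # Run / ElseRun — validated out earlier
                raise ProtocolRunError(f"unsupported block {kind!r}")

    def _run_loop(self, ev, body, loop_index: int) -> None:
        loop_key = (self.protocol_index, loop_index)
        self.loops_entered.add(loop_key)
        iteration = 0
        while True:
            if not ev.continuous and iteration >= ev.loop_count:
                break
            if ev.continuous and loop_key not in self.unchecked \
                    and not self._pending_uncheck(loop_key):
                raise ProtocolRunError(
                    f"continuous loop {loop_key[1]} has no uncheck control "
                    "event: it would run forever")
            t_before, sweeps_before = self.t, self.sweep_count
            self._run_nodes(body)
            iteration += 1
            if self.t == t_before and self.sweep_count == sweeps_before:
                # empty body cannot advance the clock; jump to the uncheck
                pending = self._pending_uncheck(loop_key)
                times = [ev2.time_s for ev2 in pending if ev2.time_s is not None]
                if ev.continuous and times:
                    self.t = max(self.t, min(times))
                elif ev.continuous:
                    raise ProtocolRunError(
                        f"continuous loop {loop_key[1]} makes no progress")
            self.process_controls()
            if loop_key in self.unchecked:
                break

    def finalize(self) -> None:
        for i, ev in enumerate(self.controls):
            if not self.fired[i] and ev.action == "uncheck_loop":
                key = (ev.protocol_index if ev.protocol_index is not None else 0,
                       ev.loop_index or 0)
                if key not in self.loops_entered:
                    self.record.warnings.append(
                        f"uncheck control for loop {key} never reached")
        if not self.set_ch_to_last:
            for line, ch in list(self.channel_state.items()):
                if ch != 0 and self.rig.controller(line) is not None:
                    self._emit_switch(line, 0)
        self.record.end_time_s = self.t


def _build_tree(events, i, counters):
    """Nest the flat event list into (leaf|loop|runonce, event, children,
    index) nodes.  Loop and RunOnce blocks get stable indices in script
    order (``counters`` = [next_loop_idx, next_runonce_idx])."""
    nodes = []
    while i < len(events):
        ev = events[i]
        if ev.kind in ("Loop", "RunOnce", "Run", "ElseRun"):
            if ev.kind == "Loop":
                idx = counters[0]
                counters[0] += 1
            elif ev.kind == "RunOnce":
                idx = counters[1]
                counters[1] += 1
            else:
                idx = -1
            children, i, counters = _build_tree(events, i + 1, counters)
            kind = {"Loop": "loop", "RunOnce": "runonce"}.get(ev.kind, ev.kind)
            nodes.append((kind, ev, children, idx))
        elif ev.kind.startswith("End"):
            return nodes, i + 1, counters
        else:
            nodes.append(("leaf", ev))
            i += 1
    return nodes, i, counters


def _check(script: ProtocolScript, rig: RigConfig) -> None:
    issues = validate_protocol(script, rig)
    if issues:
        raise ProtocolRunError(
            f"{script.name}: " + "; ".join(issues))


def run_protocol(script: ProtocolScript, rig: RigConfig,
                 controls: list[ControlEvent] | None = None,
                 inter_sweep_interval_s: float | None = None,
                 seed: int = 0) -> ExperimentRecord:
    """Execute one protocol script and return the experiment record."""
    _check(script, rig)
    runner = _Runner(rig, controls or [], inter_sweep_interval_s, seed)
    if isinstance(rig.biology, SliceModel):
        rig.biology.reset()
    runner.run_script(script)
    runner.finalize()
    return runner.record


def run_linked(plans: list[tuple[ProtocolScript, bool]], rig: RigConfig,
               controls: list[ControlEvent] | None = None,
               inter_sweep_interval_s: float | None = None,
               seed: int = 0) -> ExperimentRecord:
    """Execute a chain of linked protocols in one timeline.

    ``plans`` holds (script, autostart) pairs; the first protocol always
    starts.  A protocol with autostart False waits for a ``start_protocol``
    control event (time-triggered); without one the run ends there.
    """
    for script, _ in plans:
        _check(script, rig)
    runner = _Runner(rig, controls or [], inter_sweep_interval_s, seed)
    if isinstance(rig.biology, SliceModel):
        rig.biology.reset()
    for k, (script, autostart) in enumerate(plans):
        runner.protocol_index = k
        if k > 0:
            runner.record.log.append(
                LogEntry(runner.t, "link", f"Loaded {script.name}"))
            if not autostart:
                starters = [
                    (i, ev) for i, ev in enumerate(runner.controls)
                    if not runner.fired[i] and ev.action == "start_protocol"
                    and (ev.protocol_index in (None, k))
                    and ev.time_s is not None]
                if not starters:
                    runner.record.warnings.append(
                        f"protocol {script.name} not auto-started and no "
                        "start control event: run ends")
                    break
                i, ev = min(starters, key=lambda p: p[1].time_s)
                runner.fired[i] = True
                runner.t = max(runner.t, ev.time_s)
            runner.record.log.append(
                LogEntry(runner.t, "link", f"Started {script.name}"))
        runner.run_script(script)
    runner.finalize()
    return runner.record


def run_linked_files(paths: list[str | Path], rig: RigConfig,
                     controls: list[ControlEvent] | None = None,
                     sweep_defs_for=None, **kwargs) -> ExperimentRecord:
    """Load protocol files and follow their link plans.

    Each file's ``[link]`` block supplies the next file's autostart flag; a
    missing file stops the run with a logged error.  ``sweep_defs_for`` may
    map a protocol name to per-script sweep definitions.
    """
    plans: list[tuple[ProtocolScript, bool]] = []
    errors: list[str] = []
    for k, path in enumerate(paths):
        path = Path(path)
        if not path.exists():
            errors.append(f"linked protocol file not found: {path}")
            break
        script = parse_protocol(path.read_text(), name=path.name)
        if sweep_defs_for is not None:
            script.sweep_defs = sweep_defs_for(script.name) or {}
        autostart = True if k == 0 else plans[-1][0].link is not None \
            and plans[-1][0].link.autostart
        plans.append((script, autostart))
    record = run_linked(plans, rig, controls, **kwargs) if plans \
        else ExperimentRecord()
    for msg in errors:
        record.log.append(LogEntry(record.end_time_s, "error", msg))
        record.warnings.append(msg)
    return record


# ---------------------------------------------------------------------------
# log and exports


def _fmt_time(t: float) -> str:
    t_int = int(t)
    return f"{t_int // 3600}:{t_int % 3600 // 60:02d}:{t_int % 60:02d}"


def emit_log(record: ExperimentRecord) -> str:
    """Format the experimental log: one line per perfusion change (with its
    time, line, channel and solution label), sweep, and protocol link."""
    return "\n".join(
        f"{_fmt_time(e.time_s)}  {e.text}" for e in record.log) + "\n"


def run_recirculation_policy(record: ExperimentRecord,
                             policy: dict[int, str],
                             line: PerfusionLine = PerfusionLine.SLOW0,
                             out_line: PerfusionLine = PerfusionLine.SLOW1,
                             ) -> list[tuple[PerfusionLine, ValveAction]]:
    """Derive a recirculation valve timeline mirroring one line's switches.

    ``policy`` maps each perfusion channel to ``"recirculate"`` (chamber
    waste returns to the reservoir) or ``"waste"``; unlisted channels
    default to waste.  Returns timed on/off actions for the diverter valve
    on ``out_line`` (bit 0): on = recirculate.
    """
    for key, val in policy.items():
        if val not in ("recirculate", "waste"):
            raise ProtocolRunError(f"bad recirculation policy {val!r} for Ch{key}")
    timeline: list[tuple[PerfusionLine, ValveAction]] = []
    state = 0
    for ln, ch, t in sorted(record.activations, key=lambda a: a[2]):
        if ln != line:
            continue
        want = 1 if policy.get(ch, "waste") == "recirculate" else 0
        if want != state:
            timeline.append((out_line, ValveAction(t, "Port2", 0, want)))
            state = want
    return timeline


def spreadsheet_frame(record: ExperimentRecord):
    """Per-sweep measurement table (the 'Spreadsheet' panel)."""
    import pandas as pd

    rows = []
    for s in record.sweeps:
        if not s.measurements:
            rows.append({"sweep_time_s": s.start_time_s, "sweep_name": s.name,
                         "measurement": None, "value": None})
        for kind, value in s.measurements.items():
            rows.append({"sweep_time_s": s.start_time_s, "sweep_name": s.name,
                         "measurement": kind, "value": value})
    return pd.DataFrame(rows)


def timeline_frame(record: ExperimentRecord):
    """Merged valve-action table across lines."""
    import pandas as pd

    rows = [{"time_s": a.time_s, "line": ln.value, "port": a.port,
             "bit": a.bit, "value": a.value}
            for ln, a in sorted(record.valve_timeline, key=lambda p: p[1].time_s)]
    return pd.DataFrame(rows)


def write_outputs(record: ExperimentRecord, out_dir: str | Path,
                  rig: RigConfig | None = None) -> None:
    """Write experiment.log, timeline.csv, spreadsheet.csv, per-sweep trace
    CSVs and (when an analog line is configured) continuous.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "experiment.log").write_text(emit_log(record))
    timeline_frame(record).to_csv(out / "timeline.csv", index=False)
    spreadsheet_frame(record).to_csv(out / "spreadsheet.csv", index=False)
    for i, s in enumerate(record.sweeps):
        frame = s.waveforms.as_frame()
        for ad, tr in s.traces.items():
            frame[ad] = np.interp(frame["time_ms"], tr.time_ms, tr.samples)
        frame.to_csv(out / f"sweep_{i:03d}_{s.name}.csv", index=False)
    if rig is not None:
        cfg = rig.controller(rig.ic1_line)
        if cfg is not None and record.end_time_s > 0:
            import pandas as pd

            t, v = record.continuous_trace(rig.ic1_line, cfg)
            pd.DataFrame({"time_s": t, "IC1_V": v}).to_csv(
                out / "continuous.csv", index=False)
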
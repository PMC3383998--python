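"""The protocol-script event language: parse, validate, serialize.

A protocol script is the ordered list of events an experiment executes —
stimulation sweeps, loops, delays and perfusion-channel changes — written in
a line-oriented text dialect (extension ``.proto``):

    # LTP experiment with automated perfusion
    MainProtocol
      Perfuse Slow0 1
      Loop 99999 continuous
        P0sweep
      EndLoop
      Perfuse Slow0 2
      T0sweep
    EndProtocol

    [labels]
    Slow0 1 = ACSF
    Slow0 2 = CaMKII Inhibitor

    [link]
    next = second_protocol.proto
    autostart = true

``Loop 99999 continuous`` is the continuous-loop idiom: the count 99999 is
the stored sentinel, but on execution the continuous flag (a checkbox in the
original instrument GUI) governs the loop — it repeats until an operator
control event unchecks it.  The ``[labels]`` block names solutions per
(line, channel); labels are echoed beside Perfuse events on serialization
and in the experimental log.  The ``[link]`` block chains a follow-on
protocol file, auto-started when ``autostart`` is true.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .perfusion import PerfusionLine
from .sweep_engine import SWEEP_NAMES, CommandStep, Epoch, PulseTrain, SweepDef

MAX_LOOP_COUNT = 99_999  # also the "loop continuously" sentinel

_OPENERS = {"Loop": "EndLoop", "RunOnce": "EndRunOnce", "Run": "EndRun",
            "ElseRun": "EndElseRun"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}


class ProtocolSyntaxError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ProtocolEvent:
    kind: str  # Loop | EndLoop | Delay | Sweep | Perfuse | RunOnce |
    #            EndRunOnce | Run | ElseRun | EndRun | EndElseRun
    loop_count: int | None = None
    continuous: bool = False
    delay_s: float | None = None
    sweep_name: str | None = None
    line: PerfusionLine | None = None
    channel: int | None = None

    def __str__(self) -> str:
        if self.kind == "Loop":
            return f"Loop {self.loop_count}" + (" continuous" if self.continuous else "")
        if self.kind == "Delay":
            d = self.delay_s
            return f"Delay {int(d) if d == int(d) else d}"
        if self.kind == "Sweep":
            return self.sweep_name or ""
        if self.kind == "Perfuse":
            return f"Perfuse {self.line.value} {self.channel}"
        return self.kind


@dataclass
class LinkPlan:
    next_protocol_path: str
    autostart: bool = False


@dataclass
class ProtocolScript:
    events: list[ProtocolEvent] = field(default_factory=list)
    labels: dict[tuple[PerfusionLine, int], str] = field(default_factory=dict)
    link: LinkPlan | None = None
    name: str = "protocol"
    # per-script sweep definitions overriding the rig's (linked protocols
    # reuse the four sweep names with different perfusion epochs)
    sweep_defs: dict = field(default_factory=dict)

    def label(self, line: PerfusionLine, channel: int) -> str:
        """Solution label for a channel, defaulting to 'Ch<n>'."""
        return self.labels.get((line, channel), f"Ch{channel}")

    def loop_events(self) -> list[int]:
        """Indices (into events) of Loop events, in script order."""
        return [i for i, e in enumerate(self.events) if e.kind == "Loop"]


# ---------------------------------------------------------------------------
# parsing

_PERFUSE_RE = re.compile(r"Perfuse\s+(\w+)\s+(\d+)$")
_LOOP_RE = re.compile(r"Loop\s+(\d+)(\s+continuous)?$")
_DELAY_RE = re.compile(r"Delay\s+([\d.]+)$")
_LABEL_RE = re.compile(r"(\w+)\s+(\d+)\s*=\s*(.+)$")


def parse_protocol(text: str, name: str = "protocol") -> ProtocolScript:
    """Parse protocol-script text into a :class:`ProtocolScript`.

    Raises :class:`ProtocolSyntaxError` (with line number) on malformed
    lines, unbalanced block nesting, out-of-range loop counts, or unknown
    sweep names.  Event order is preserved exactly.
    """
    if not text.strip():
        raise ProtocolSyntaxError("empty protocol text")
    events: list[ProtocolEvent] = []
    labels: dict[tuple[PerfusionLine, int], str] = {}
    link: LinkPlan | None = None
    section = "preamble"
    saw_main = saw_end = False
    stack: list[tuple[str, int]] = []
    link_fields: dict[str, str] = {}
    sweep_defs: dict[str, SweepDef] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            if stripped not in ("[labels]", "[link]", "[sweeps]"):
                raise ProtocolSyntaxError(f"unknown section {stripped}", line_no)
            section = stripped[1:-1]
            continue
        if section == "sweeps":
            name, sd = _parse_sweep_line(stripped, line_no)
            sweep_defs[name] = sd
            continue
        if section == "labels":
            m = _LABEL_RE.match(stripped)
            if not m:
                raise ProtocolSyntaxError("malformed label (want 'Line Ch = text')",
                                          line_no)
            try:
                pline = PerfusionLine(m.group(1))
            except ValueError:
                raise ProtocolSyntaxError(f"unknown line {m.group(1)!r}", line_no)
            labels[(pline, int(m.group(2)))] = m.group(3).strip()
            continue
        if section == "link":
            key, _, value = stripped.partition("=")
            link_fields[key.strip()] = value.strip()
            continue

        # protocol body
        if stripped == "MainProtocol":
            if saw_main:
                raise ProtocolSyntaxError("duplicate MainProtocol", line_no)
            saw_main = True
            continue
        if stripped == "EndProtocol":
            if not saw_main:
                raise ProtocolSyntaxError("EndProtocol before MainProtocol", line_no)
            if stack:
                kind, opened = stack[-1]
                raise ProtocolSyntaxError(
                    f"{kind} opened at line {opened} never closed", line_no)
            saw_end = True
            continue
        if not saw_main or saw_end:
            raise ProtocolSyntaxError(
                f"event {stripped!r} outside MainProtocol/EndProtocol", line_no)

        word = stripped.split()[0]
        if word == "Loop":
            m = _LOOP_RE.match(stripped)
            if not m:
                raise ProtocolSyntaxError("malformed Loop (want 'Loop N [continuous]')",
                                          line_no)
            count = int(m.group(1))
            if not 1 <= count <= MAX_LOOP_COUNT:
                raise ProtocolSyntaxError(
                    f"loop count {count} out of 1..{MAX_LOOP_COUNT}", line_no)
            events.append(ProtocolEvent("Loop", loop_count=count,
                                        continuous=bool(m.group(2))))
            stack.append(("Loop", line_no))
        elif word in ("RunOnce", "Run", "ElseRun"):
            events.append(ProtocolEvent(word))
            stack.append((word, line_no))
        elif word in _CLOSERS:
            if not stack or stack[-1][0] != _CLOSERS[word]:
                raise ProtocolSyntaxError(f"unmatched {word}", line_no)
            stack.pop()
            events.append(ProtocolEvent(word))
        elif word == "Delay":
            m = _DELAY_RE.match(stripped)
            if not m:
                raise ProtocolSyntaxError("malformed Delay (want 'Delay seconds')",
                                          line_no)
            events.append(ProtocolEvent("Delay", delay_s=float(m.group(1))))
        elif word == "Perfuse":
            m = _PERFUSE_RE.match(stripped)
            if not m:
                raise ProtocolSyntaxError("malformed Perfuse (want 'Perfuse Line Ch')",
                                          line_no)
            try:
                pline = PerfusionLine(m.group(1))
            except ValueError:
                raise ProtocolSyntaxError(f"unknown perfusion line {m.group(1)!r}",
                                          line_no)
            events.append(ProtocolEvent("Perfuse", line=pline,
                                        channel=int(m.group(2))))
        elif word in SWEEP_NAMES:
            if stripped != word:
                raise ProtocolSyntaxError("sweep event takes no arguments", line_no)
            events.append(ProtocolEvent("Sweep", sweep_name=word))
        else:
            raise ProtocolSyntaxError(f"unknown event {word!r}", line_no)

    if not saw_main:
        raise ProtocolSyntaxError("missing MainProtocol line")
    if not saw_end:
        raise ProtocolSyntaxError("missing EndProtocol line")
    if link_fields:
        if not link_fields.get("next"):
            raise ProtocolSyntaxError("[link] block without a 'next' path")
        link = LinkPlan(link_fields["next"],
                        link_fields.get("autostart", "false").lower()
                        in ("true", "1", "yes"))
    return ProtocolScript(events=events, labels=labels, link=link, name=name,
                          sweep_defs=sweep_defs)


def _parse_sweep_line(stripped: str, line_no: int) -> tuple[str, SweepDef]:
    """One ``[sweeps]`` entry, e.g.::

        P0sweep = duration_ms=3000 rate_hz=2000 epochs=-1:1000,4:1000,-1:1000
        T0sweep = duration_ms=1200 rate_hz=10000 s0=10:100:10

    ``s0``/``s1`` pulse trains are ``onset:count:interval[:width]`` (ms);
    ``epochs`` are three ``amplitude:duration_ms`` items (amplitude −1 =
    hold the current channel); ``ic0`` steps are ``onset:duration:volts``.
    """
    name, _, rest = stripped.partition("=")
    name = name.strip()
    kwargs: dict = {}
    try:
        for tok in rest.split():
            key, _, val = tok.partition("=")
            if key == "duration_ms":
                kwargs["duration_ms"] = float(val)
            elif key == "rate_hz":
                kwargs["sample_rate_hz"] = float(val)
            elif key in ("s0", "s1"):
                p = [float(x) for x in val.split(":")]
                kwargs[f"{key}_train"] = PulseTrain(
                    p[0], int(p[1]), p[2], p[3] if len(p) > 3 else 0.1)
            elif key == "epochs":
                eps = []
                for item in val.split(","):
                    amp, dur = item.split(":")
                    eps.append(Epoch(float(dur), float(amp)))
                kwargs["ic1_epochs"] = tuple(eps)
            elif key == "ic0":
                kwargs["ic0_steps"] = [
                    CommandStep(*(float(x) for x in item.split(":")))
                    for item in val.split(",")]
            else:
                raise ProtocolSyntaxError(f"unknown sweep field {key!r}", line_no)
        return name, SweepDef(name=name, **kwargs)
    except (ValueError, TypeError) as err:
        if isinstance(err, ProtocolSyntaxError):
            raise
        raise ProtocolSyntaxError(f"malformed sweep definition: {err}", line_no)


# ---------------------------------------------------------------------------
# validation

def validate_protocol(script: ProtocolScript, rig=None) -> list[str]:
    """Return a list of issues (empty iff the script can run on ``rig``).

    ``rig`` needs ``controller(line)`` returning a controller config or
    None, and a ``sweep_defs`` mapping; pass None to check structure only.
    """
    issues: list[str] = []
    depth = 0
    for i, e in enumerate(script.events):
        if e.kind in _OPENERS:
            depth += 1
            if e.kind in ("Run", "ElseRun"):
                issues.append(f"event {i}: {e.kind} is not supported")
        elif e.kind in _CLOSERS:
            depth -= 1
            if depth < 0:
                issues.append(f"event {i}: unmatched {e.kind}")
                depth = 0
        elif e.kind == "Loop" and not 1 <= (e.loop_count or 0) <= MAX_LOOP_COUNT:
            issues.append(f"event {i}: loop count out of range")
        elif e.kind == "Perfuse" and rig is not None:
            cfg = rig.controller(e.line)
            if cfg is None:
                issues.append(f"event {i}: no controller configured for "
                              f"{e.line.value}")
            elif not 0 <= e.channel <= cfg.n_channels:
                issues.append(
                    f"event {i}: channel {e.channel} exceeds {e.line.value}'s "
                    f"{cfg.n_channels} channels")
        elif e.kind == "Sweep" and rig is not None:
            if e.sweep_name not in script.sweep_defs \
                    and e.sweep_name not in rig.sweep_defs:
                issues.append(f"event {i}: sweep {e.sweep_name} not defined on rig")
    if depth != 0:
        issues.append("unbalanced block nesting at EndProtocol")
    if script.link is not None and script.link.autostart \
            and not script.link.next_protocol_path:
        issues.append("autostart link with empty protocol path")
    return issues


# ---------------------------------------------------------------------------
# serialization

def serialize_protocol(script: ProtocolScript) -> str:
    """Render a script back to dialect text; parse∘serialize is identity on
    structure.  Continuous loops always serialize with the 99999 sentinel
    count; solution labels are echoed as comments beside Perfuse events."""
    lines = ["MainProtocol"]
    depth = 1
    for e in script.events:
        if e.kind in _CLOSERS:
            depth -= 1
        if e.kind == "Loop" and e.continuous:
            e = replace(e, loop_count=MAX_LOOP_COUNT)
        text = "  " * depth + str(e)
        if e.kind == "Perfuse":
            text += f"  # {script.label(e.line, e.channel)}"
        lines.append(text)
        if e.kind in _OPENERS:
            depth += 1
    lines.append("EndProtocol")
    if script.sweep_defs:
        lines += ["", "[sweeps]"]
        for name in sorted(script.sweep_defs):
            lines.append(_format_sweep_def(script.sweep_defs[name]))
    if script.labels:
        lines += ["", "[labels]"]
        for (pline, ch), label in sorted(
                script.labels.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            lines.append(f"{pline.value} {ch} = {label}")
    if script.link is not None:
        lines += ["", "[link]",
                  f"next = {script.link.next_protocol_path}",
                  f"autostart = {'true' if script.link.autostart else 'false'}"]
    return "\n".join(lines) + "\n"


def _num(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else str(x)


def _format_sweep_def(sd: SweepDef) -> str:
    parts = [f"{sd.name} = duration_ms={_num(sd.duration_ms)}",
             f"rate_hz={_num(sd.sample_rate_hz)}"]
    for key, train in (("s0", sd.s0_train), ("s1", sd.s1_train)):
        if train is not None:
            spec = f"{_num(train.onset_ms)}:{train.pulse_count}:" \
                   f"{_num(train.interval_ms)}"
            if train.pulse_width_ms != 0.1:
                spec += f":{_num(train.pulse_width_ms)}"
            parts.append(f"{key}={spec}")
    if sd.ic0_steps:
        parts.append("ic0=" + ",".join(
            f"{_num(s.onset_ms)}:{_num(s.duration_ms)}:{_num(s.amplitude_v)}"
            for s in sd.ic0_steps))
    if sd.ic1_epochs is not None:
        parts.append("epochs=" + ",".join(
            f"{_num(e.amplitude)}:{_num(e.duration_ms)}" for e in sd.ic1_epochs))
    return " ".join(parts)
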
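"""Perfusion controller encodings, valve-action planning and design arithmetic.

A perfusion controller turns one of several solution reservoirs onto the
recording chamber.  Controllers are driven three ways:

* ``analog``    — one voltage line, ``channel x volts_per_channel`` volts,
                  exactly one valve open at a time (8-channel units are
                  typically 1 V/channel, 16-channel units 0.5 V/channel);
* ``binary4``   — a 4-bit binary channel number (8, 15 or 16 channels,
                  one valve open at a time);
* ``valvebits`` — one digital bit per valve, so several valves may be open
                  at once.  This is what pre-flush switching needs.

Channel 0 is the universal "all off" code in every mode.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class PerfusionLine(str, enum.Enum):
    """The four independently controllable perfusion lines.

    Slow lines are driven by static digital ports and may change only
    *between* sweeps; Fast lines are driven by sweep-clocked outputs and may
    also change *during* a sweep.
    """

    SLOW0 = "Slow0"
    SLOW1 = "Slow1"
    FAST0 = "Fast0"
    FAST1 = "Fast1"

    @property
    def is_fast(self) -> bool:
        return self in (PerfusionLine.FAST0, PerfusionLine.FAST1)


class Binary4Convention(str, enum.Enum):
    """How a 4-bit binary code maps to channels.

    ``OFF_CODE_ZERO_15CH`` reserves 0000 for all-off, leaving 15 usable
    channels; ``FULL_16CH`` maps channels 1–16 to codes 0–15 with no off
    code; ``EIGHT_CH`` uses codes 0–8 with 0000 = all off.
    """

    OFF_CODE_ZERO_15CH = "off_code_zero_15ch"
    FULL_16CH = "full_16ch"
    EIGHT_CH = "8ch"


class PerfusionError(ValueError):
    """Raised for invalid channels, modes or switch-plan requests."""


@dataclass
class ControllerConfig:
    """Output encoding of one perfusion line's controller.

    valve_switch_time_ms is a pure latency annotation (≈100 ms for pinch
    valves, ≈4 ms for fast solenoid valves); plans carry it so downstream
    transport models can account for it.
    """

    line: PerfusionLine
    mode: str = "valvebits"  # analog | binary4 | valvebits
    n_channels: int = 8
    volts_per_channel: float = 1.0
    valves_per_channel: int = 1  # 2 => pre-flush (chamber + flush valve)
    port: str = "Port1"
    bit_base: int = 0
    valve_switch_time_ms: float = 100.0
    binary4_convention: Binary4Convention = Binary4Convention.EIGHT_CH
    flush_duration_s: float = 10.0
    # True: sweep-epoch amplitudes are literal volts; False (default):
    # channel-number units converted by volts_per_channel at output.
    amplitude_is_volts: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.line, str):
            self.line = PerfusionLine(self.line)
        if isinstance(self.binary4_convention, str):
            self.binary4_convention = Binary4Convention(self.binary4_convention)
        if self.mode not in ("analog", "binary4", "valvebits"):
            raise PerfusionError(f"unknown controller mode {self.mode!r}")
        if self.n_channels < 1:
            raise PerfusionError("controller needs at least one channel")
        if self.valves_per_channel not in (1, 2):
            raise PerfusionError("valves_per_channel must be 1 or 2")
        if self.valves_per_channel == 2 and self.n_channels > self.port_bits // 2:
            raise PerfusionError(
                f"{self.n_channels} pre-flush channels need "
                f"{2 * self.n_channels} bits but {self.port} has {self.port_bits}"
            )

    @property
    def port_bits(self) -> int:
        return 16 if self.port == "Port1+2" else 8

    def check_channel(self, channel: int) -> None:
        if not 0 <= channel <= self.n_channels:
            raise PerfusionError(
                f"channel {channel} out of range 0..{self.n_channels} "
                f"({self.line.value})"
            )


@dataclass(frozen=True)
class ValveAction:
    """One timed controller output change.

    ``bit`` is None for analog actions, in which case ``value`` is volts;
    for digital actions ``value`` is 1 (on) or 0 (off).
    """

    time_s: float
    port: str
    bit: int | None
    value: float

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise PerfusionError("valve action before t=0")


@dataclass
class SwitchPlan:
    """The ordered valve/voltage actions realizing one channel change."""

    actions: list[ValveAction]
    from_channel: int
    to_channel: int
    mode: str
    line: PerfusionLine = PerfusionLine.SLOW0

    def __post_init__(self) -> None:
        times = [a.time_s for a in self.actions]
        if any(b < a for a, b in zip(times, times[1:])):
            raise PerfusionError("switch-plan actions out of time order")

    def shifted(self, t0_s: float) -> list[ValveAction]:
        """The plan's actions offset to absolute time ``t0_s``."""
        return [
            ValveAction(a.time_s + t0_s, a.port, a.bit, a.value)
            for a in self.actions
        ]

    def open_valves_after(self) -> set[int]:
        """Digital bits left on once every action has executed."""
        state: dict[int, float] = {}
        for a in self.actions:
            if a.bit is not None:
                state[a.bit] = a.value
        return {bit for bit, v in state.items() if v}

    @property
    def duration_s(self) -> float:
        return self.actions[-1].time_s if self.actions else 0.0


@dataclass(frozen=True)
class TubingSegment:
    length_cm: float
    inner_diameter_mm: float
    role: str = "junction_to_manifold"
    # roles: reservoir_to_junction | junction_to_manifold | manifold_to_chamber

    def __post_init__(self) -> None:
        if self.length_cm < 0 or self.inner_diameter_mm <= 0:
            raise PerfusionError("tubing segment needs positive dimensions")


@dataclass
class StepperConfig:
    """Motorized tube positioner moving 2–3 side-by-side outflow tubes.

    Tube0 is fed by Slow0, Tube1 by Slow1, Tube2 by Fast1.  The stepper
    itself is driven by the Fast0 analog output at 1 V per tube position, so
    its stream can be swapped within a sweep (≈1 ms for a piezo device).
    """

    tubes: tuple[int, ...] = (0, 1, 2)
    fast0_volts_per_tube: float = 1.0
    move_time_ms: float = 1.0
    feeding_line: dict[int, PerfusionLine] = field(
        default_factory=lambda: {
            0: PerfusionLine.SLOW0,
            1: PerfusionLine.SLOW1,
            2: PerfusionLine.FAST1,
        }
    )

    def __post_init__(self) -> None:
        if any(t not in (0, 1, 2) for t in self.tubes):
            raise PerfusionError("tube index must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# channel -> output encodings


def encode_analog(channel: int, cfg: ControllerConfig) -> float:
    """Analog command voltage selecting ``channel`` (0 = all off = 0 V)."""
    cfg.check_channel(channel)
    return channel * cfg.volts_per_channel


def encode_binary4(
    channel: int,
    convention: Binary4Convention | str = Binary4Convention.OFF_CODE_ZERO_15CH,
) -> tuple[int, int, int, int]:
    """4-bit binary code for ``channel``, LSB-first bit0..bit3."""
    convention = Binary4Convention(convention)
    if convention is Binary4Convention.FULL_16CH:
        if not 1 <= channel <= 16:
            raise PerfusionError(f"channel {channel} out of range 1..16")
        code = channel - 1
    elif convention is Binary4Convention.EIGHT_CH:
        if not 0 <= channel <= 8:
            raise PerfusionError(f"channel {channel} out of range 0..8")
        code = channel
    else:
        if not 0 <= channel <= 15:
            raise PerfusionError(f"channel {channel} out of range 0..15")
        code = channel
    return tuple((code >> i) & 1 for i in range(4))  # type: ignore[return-value]


def encode_valvebits(channel: int, cfg: ControllerConfig) -> int:
    """One-hot valve byte: channel n drives bit n-1; channel 0 = all off."""
    cfg.check_channel(channel)
    if channel == 0:
        return 0
    return 1 << (cfg.bit_base + channel - 1)


# ---------------------------------------------------------------------------
# switch planning


def _chamber_bit(cfg: ControllerConfig, channel: int) -> int:
    return cfg.bit_base + channel - 1


def _flush_bit(cfg: ControllerConfig, channel: int) -> int:
    # chamber valves occupy bits 0..n-1, flush valves the next block, so a
    # 4-channel unit has Ch2's flush valve on bit 5.
    return cfg.bit_base + cfg.n_channels + channel - 1


def plan_standard_switch(
    from_ch: int, to_ch: int, cfg: ControllerConfig
) -> SwitchPlan:
    """Simultaneous close-old/open-new: the bolus of stale line contents
    between reservoir and manifold flows straight into the chamber."""
    cfg.check_channel(from_ch)
    cfg.check_channel(to_ch)
    actions: list[ValveAction] = []
    if from_ch != to_ch:
        if cfg.mode == "analog":
            actions.append(
                ValveAction(0.0, cfg.port, None, encode_analog(to_ch, cfg))
            )
        elif cfg.mode == "binary4":
            old = encode_binary4(from_ch, cfg.binary4_convention)
            new = encode_binary4(to_ch, cfg.binary4_convention)
            for i in range(4):
                if old[i] != new[i]:
                    actions.append(
                        ValveAction(0.0, cfg.port, cfg.bit_base + i, new[i])
                    )
        else:
            if from_ch != 0:
                actions.append(
                    ValveAction(0.0, cfg.port, _chamber_bit(cfg, from_ch), 0)
                )
            if to_ch != 0:
                actions.append(
                    ValveAction(0.0, cfg.port, _chamber_bit(cfg, to_ch), 1)
                )
    return SwitchPlan(actions, from_ch, to_ch, cfg.mode, cfg.line)


def plan_preflush_switch(
    from_ch: int,
    to_ch: int,
    flush_duration_s: float | None = None,
    cfg: ControllerConfig | None = None,
) -> SwitchPlan:
    """Pre-flush switch: open the new line's flush-to-waste valve first to
    clear stale solution down to the T-junction, then swap the chamber
    valves while closing the flush valve.  Requires 2 valves/channel."""
    if cfg is None:
        cfg = ControllerConfig(
            PerfusionLine.SLOW0, mode="valvebits", n_channels=4,
            valves_per_channel=2,
        )
    if cfg.valves_per_channel != 2:
        raise PerfusionError("pre-flush needs a 2 valves/channel controller")
    cfg.check_channel(from_ch)
    cfg.check_channel(to_ch)
    t_flush = cfg.flush_duration_s if flush_duration_s is None else flush_duration_s
    if t_flush <= 0:
        raise PerfusionError("flush duration must be positive")
    actions: list[ValveAction] = []
    if from_ch != to_ch:
        if to_ch != 0:
            actions.append(ValveAction(0.0, cfg.port, _flush_bit(cfg, to_ch), 1))
            actions.append(ValveAction(t_flush, cfg.port, _flush_bit(cfg, to_ch), 0))
            actions.append(
                ValveAction(t_flush, cfg.port, _chamber_bit(cfg, to_ch), 1)
            )
        if from_ch != 0:
            actions.append(
                ValveAction(t_flush if to_ch != 0 else 0.0, cfg.port,
                            _chamber_bit(cfg, from_ch), 0)
            )
    return SwitchPlan(actions, from_ch, to_ch, "preflush", cfg.line)


def plan_flow_to_waste_switch(
    from_ch: int, to_ch: int, cfg: ControllerConfig
) -> SwitchPlan:
    """Continuous-flow-to-waste switch with three-way NO/NC pinch valves.

    Deselected lines flow to waste through the Normally Open path, keeping
    them fresh; activating a channel's valve diverts its Y-junction flow to
    the manifold.  One valve per channel; a single simultaneous toggle."""
    cfg.check_channel(from_ch)
    cfg.check_channel(to_ch)
    actions: list[ValveAction] = []
    if from_ch != to_ch:
        if from_ch != 0:
            actions.append(
                ValveAction(0.0, cfg.port, _chamber_bit(cfg, from_ch), 0)
            )
        if to_ch != 0:
            actions.append(
                ValveAction(0.0, cfg.port, _chamber_bit(cfg, to_ch), 1)
            )
    return SwitchPlan(actions, from_ch, to_ch, "flow_to_waste", cfg.line)


def stepper_move(tube: int, cfg: StepperConfig) -> ValveAction:
    """Analog Fast0 command positioning the stepper over ``tube``."""
    if tube not in cfg.tubes:
        raise PerfusionError(f"tube {tube} not present in this stepper config")
    return ValveAction(0.0, "AnalogOut1", None, tube * cfg.fast0_volts_per_tube)


# ---------------------------------------------------------------------------
# design arithmetic


def dead_volume(seg: TubingSegment) -> float:
    """Stale-solution volume of a tubing segment, in ml (= cm^3)."""
    radius_cm = seg.inner_diameter_mm / 10.0 / 2.0
    return math.pi * radius_cm**2 * seg.length_cm


def solutions_required(
    n_agonists: int, n_antagonists: int, antagonist_stays_bound: bool
) -> int:
    """Distinct solutions for an agonist/antagonist concentration–response
    design.

    A tightly bound antagonist survives agonist application, so agonist-only
    and antagonist-only solutions suffice (n_ag + n_antag).  A loosely bound
    antagonist is displaced, so every agonist solution must also contain the
    antagonist: n_antag pre-perfusion solutions plus one combined solution
    per (agonist, antagonist) pair.
    """
    if n_agonists < 0 or n_antagonists < 0:
        raise PerfusionError("solution counts must be non-negative")
    if antagonist_stays_bound:
        return n_agonists + n_antagonists
    return n_antagonists + n_agonists * n_antagonists


def max_solutions(lines: int, channels_per_line: int) -> int:
    """Solution capacity of a multi-line (stepper) perfusion setup."""
    if lines not in (1, 2, 3):
        raise PerfusionError("1, 2 or 3 perfusion lines supported")
    return lines * channels_per_line
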
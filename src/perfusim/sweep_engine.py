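"""Render sweep definitions into sampled stimulus/command waveforms.

A *sweep* is one timed stimulation + acquisition episode.  Four named sweeps
exist (P0sweep/P1sweep single-pulse, T0sweep/T1sweep train variants), each
rendered to:

* ``S0``/``S1`` — digital stimulus-isolator trigger trains;
* ``IC0`` — analog command steps (patch-clamp command voltage);
* ``IC1`` — analog epochs, normally routed to a Fast perfusion controller so
  solutions can change *during* the sweep.  An epoch amplitude of −1 is a
  sentinel meaning "hold whatever channel the last Fast Perfuse event set".

Pulse edges are scheduled at exact times (onset + k·interval, no cumulative
rounding); the sampled series quantizes those edges at the sweep's sample
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .perfusion import (
    Binary4Convention,
    ControllerConfig,
    PerfusionError,
    encode_analog,
    encode_binary4,
)

SENTINEL_HOLD = -1.0  # epoch amplitude meaning "keep the current channel"

SWEEP_NAMES = ("P0sweep", "P1sweep", "T0sweep", "T1sweep")


class SweepError(ValueError):
    """Raised for sweep definitions that cannot be rendered."""


@dataclass(frozen=True)
class PulseTrain:
    onset_ms: float
    pulse_count: int
    interval_ms: float
    pulse_width_ms: float = 0.1

    def edge_times_ms(self) -> list[float]:
        """Exact rising-edge times; placement is onset + k·interval."""
        return [self.onset_ms + k * self.interval_ms for k in range(self.pulse_count)]


@dataclass(frozen=True)
class CommandStep:
    onset_ms: float
    duration_ms: float
    amplitude_v: float


@dataclass(frozen=True)
class Epoch:
    """One third of the IC1 perfusion command (Step0/Step1/Step2)."""

    duration_ms: float
    amplitude: float  # channel-number units, or SENTINEL_HOLD


@dataclass
class SweepDef:
    name: str
    duration_ms: float = 5000.0
    sample_rate_hz: float = 10_000.0
    s0_train: PulseTrain | None = None
    s1_train: PulseTrain | None = None
    ic0_steps: list[CommandStep] = field(default_factory=list)
    ic1_epochs: tuple[Epoch, Epoch, Epoch] | None = None

    def __post_init__(self) -> None:
        if self.name not in SWEEP_NAMES:
            raise SweepError(f"unknown sweep name {self.name!r}")
        if self.duration_ms <= 0 or self.sample_rate_hz <= 0:
            raise SweepError("sweep needs positive duration and sample rate")
        for train in (self.s0_train, self.s1_train):
            if train is None:
                continue
            end = train.edge_times_ms()[-1] + train.pulse_width_ms
            if train.onset_ms < 0 or end > self.duration_ms:
                raise SweepError(
                    f"{self.name}: pulse train [{train.onset_ms}, {end}] ms "
                    f"exceeds sweep duration {self.duration_ms} ms"
                )
        if self.ic1_epochs is not None:
            self.ic1_epochs = tuple(self.ic1_epochs)  # type: ignore[assignment]
            if len(self.ic1_epochs) != 3:
                raise SweepError("IC1 takes exactly 3 epochs (Step0/Step1/Step2)")
            total = sum(e.duration_ms for e in self.ic1_epochs)
            if total > self.duration_ms + 1e-9:
                raise SweepError(
                    f"epoch durations {total} ms exceed sweep {self.duration_ms} ms"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate_hz / 1000.0))

    def epoch_channels(self, current_channel: int) -> list[tuple[float, float, int]]:
        """(start_ms, end_ms, channel) per IC1 epoch with sentinels resolved."""
        if self.ic1_epochs is None:
            return []
        out, t = [], 0.0
        for e in self.ic1_epochs:
            ch = current_channel if e.amplitude == SENTINEL_HOLD else int(e.amplitude)
            out.append((t, t + e.duration_ms, ch))
            t += e.duration_ms
        return out


@dataclass
class SweepWaveforms:
    """Sampled outputs of one rendered sweep (all series equal length)."""

    time_ms: np.ndarray
    s0: np.ndarray
    s1: np.ndarray
    ic0_v: np.ndarray
    ic1_v: np.ndarray
    s0_edges_ms: list[float]
    s1_edges_ms: list[float]
    fast_sync_bits: np.ndarray | None = None  # (n, 4) 0/1 when configured

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "S0": self.s0,
                "S1": self.s1,
                "IC0_V": self.ic0_v,
                "IC1_V": self.ic1_v,
            }
        )


def resolve_epoch_voltage(
    amplitude: float, current_channel: int, cfg: ControllerConfig
) -> float:
    """Voltage a sweep epoch puts on the perfusion command output.

    The sentinel −1 holds the channel selected by the last Fast Perfuse
    event.  Any other amplitude selects a channel: by default it is in
    channel-number units (1 unit = 1 channel) converted through the
    controller's volts/channel, so 15 selects Ch15 on both a 1 V/channel and
    a 0.5 V/channel controller; with ``cfg.amplitude_is_volts`` the value is
    emitted verbatim (and must land on a valid channel voltage).
    """
    if amplitude == SENTINEL_HOLD:
        return encode_analog(current_channel, cfg)
    if cfg.amplitude_is_volts:
        ch = amplitude / cfg.volts_per_channel
        if abs(ch - round(ch)) > 1e-9 or not 0 <= round(ch) <= cfg.n_channels:
            raise PerfusionError(
                f"{amplitude} V maps to no valid channel at "
                f"{cfg.volts_per_channel} V/channel"
            )
        return amplitude
    ch = int(amplitude)
    if ch != amplitude or not 0 <= ch <= cfg.n_channels:
        raise PerfusionError(f"epoch amplitude {amplitude} selects no valid channel")
    return encode_analog(ch, cfg)


def render_sweep(
    sweep: SweepDef,
    current_fast_channel: int = 0,
    cfg: ControllerConfig | None = None,
) -> SweepWaveforms:
    """Sample all outputs of one sweep.

    ``current_fast_channel`` is the channel held by the controlling Fast
    line between sweeps; sentinel epochs resolve to it.  ``cfg`` is that
    line's controller (defaults to an 8-channel 1 V/channel analog unit).
    """
    if cfg is None:
        cfg = ControllerConfig(line="Fast0", mode="analog", n_channels=16)
    n = sweep.n_samples
    dt_ms = 1000.0 / sweep.sample_rate_hz
    t = np.arange(n) * dt_ms

    def digitize(train: PulseTrain | None) -> tuple[np.ndarray, list[float]]:
        series = np.zeros(n, dtype=np.int8)
        if train is None:
            return series, []
        edges = train.edge_times_ms()
        for t0 in edges:
            i0 = int(round(t0 / dt_ms))
            i1 = max(i0 + 1, int(round((t0 + train.pulse_width_ms) / dt_ms)))
            series[i0:i1] = 1
        return series, edges

    s0, s0_edges = digitize(sweep.s0_train)
    s1, s1_edges = digitize(sweep.s1_train)

    ic0 = np.zeros(n)
    for step in sweep.ic0_steps:
        i0 = int(round(step.onset_ms / dt_ms))
        i1 = int(round((step.onset_ms + step.duration_ms) / dt_ms))
        ic0[i0:i1] = step.amplitude_v

    ic1 = np.full(n, encode_analog(current_fast_channel, cfg))
    sync = None
    spans = sweep.epoch_channels(current_fast_channel)
    if spans:
        sync = np.zeros((n, 4), dtype=np.int8)
        for start_ms, end_ms, ch in spans:
            i0 = int(round(start_ms / dt_ms))
            i1 = int(round(end_ms / dt_ms))
            ic1[i0:i1] = encode_analog(ch, cfg)
            bits = encode_binary4(
                ch,
                cfg.binary4_convention
                if cfg.mode == "binary4"
                else Binary4Convention.OFF_CODE_ZERO_15CH,
            )
            sync[i0:i1] = bits
        # trailing gap after the last epoch holds the between-sweep channel
    return SweepWaveforms(t, s0, s1, ic0, ic1, s0_edges, s1_edges, sync)


def count_pulses(w: SweepWaveforms, output: str = "S0") -> int:
    """Number of 0→1 transitions on a digital output."""
    series = {"S0": w.s0, "S1": w.s1}[output]
    if len(series) == 0:
        return 0
    rises = np.flatnonzero(np.diff(series.astype(np.int8)) == 1).size
    return int(rises + (1 if series[0] == 1 else 0))
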
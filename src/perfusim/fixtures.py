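"""Worked example protocols and rigs.

These builders reproduce the canonical experiments the simulator is aimed
at, and double as test fixtures:

* a basic slice LTP experiment — circular baseline scripting with manually
  evoked induction trains, the same experiment with a RunOnce block, and the
  fully sequential version (``fig2a``/``fig2b``/``fig2c`` in the builders'
  naming: a/b/c variants of the same stimulation);
* the sequential slice experiment with automated perfusion — baseline in
  control solution (Ch1 ACSF), a kinase-inhibitor application (Ch2) covering
  the first induction train, washout, and a second train (``slice_ltp``);
* single-line fast-perfusion patch-clamp experiments: 4 agonists × 4
  tightly bound antagonists on one 8-channel controller, and the 3-protocol
  linked design delivering 15 solutions (3 antagonists + 12
  agonist+antagonist mixes) on a 16-channel controller;
* a triple-line stepper experiment where a Fast-line analog output moves
  the tube bathing the cell within a sweep.
"""

from __future__ import annotations

from pathlib import Path

from .executor import ControlEvent
from .perfusion import (
    ControllerConfig,
    PerfusionLine,
    StepperConfig,
    TubingSegment,
)
from .protocol_model import ProtocolScript, parse_protocol
from .rig import RigConfig
from .sweep_engine import Epoch, PulseTrain, SweepDef
from .virtual_rig import PatchModel, SliceModel, TransportModel

# agonist / antagonist concentration ladders (µM) used by the patch rigs
AGONIST_UM = (1.0, 3.0, 10.0, 30.0)
ANTAGONIST_UM = (0.0, 2.5, 5.0, 10.0)  # first = none (plain bath solution)


# ---------------------------------------------------------------------------
# slice experiments

CIRCULAR_BASELINE = """\
# circular script: continuous baseline loop; induction trains are evoked
# manually with single-sweep run controls
MainProtocol
  Loop 99999 continuous
    P0sweep
  EndLoop
EndProtocol
"""

CIRCULAR_RUNONCE = """\
# circular script with a RunOnce block: checking its Run control delivers
# one induction train inside the baseline loop
MainProtocol
  Loop 99999 continuous
    P0sweep
    RunOnce
      T0sweep
    EndRunOnce
  EndLoop
EndProtocol
"""

SEQUENTIAL_LTP = """\
# sequential script: uncheck the baseline loop once stable, then the whole
# stimulation sequence runs unattended
MainProtocol
  Loop 99999 continuous
    P0sweep
  EndLoop
  T0sweep
  Loop 11
    P0sweep
  EndLoop
  T0sweep
  Loop 8
    P0sweep
  EndLoop
EndProtocol
"""

SLICE_LTP_PERFUSION = """\
# sequential slice LTP experiment with automated perfusion: inhibitor on
# for the first train, washed out for the second
MainProtocol
  Perfuse Slow0 1
  Loop 99999 continuous
    P0sweep
  EndLoop
  Perfuse Slow0 2
  Loop 8
    P0sweep
  EndLoop
  T0sweep
  Loop 3
    P0sweep
  EndLoop
  Perfuse Slow0 1
  Loop 8
    P0sweep
  EndLoop
  T0sweep
  Loop 8
    P0sweep
  EndLoop
EndProtocol

[labels]
Slow0 1 = ACSF
Slow0 2 = CaMKII Inhibitor
"""


def slice_sweep_defs() -> dict[str, SweepDef]:
    """Single-pulse P0 sweep and a 100-pulse, 100 Hz T0 induction train."""
    return {
        "P0sweep": SweepDef("P0sweep", duration_ms=200.0, sample_rate_hz=10_000.0,
                            s0_train=PulseTrain(10.0, 1, 10.0)),
        "T0sweep": SweepDef("T0sweep", duration_ms=1200.0, sample_rate_hz=10_000.0,
                            s0_train=PulseTrain(10.0, 100, 10.0)),
    }


def slice_rig(system: str = "standard", noise_sd: float = 0.0,
              seed: int = 0) -> RigConfig:
    """8-channel slice chamber rig: one Slow0 line, valve-per-channel
    digital controller, standard (or pre-flush / flow-to-waste) hydraulics,
    and a synthetic slice whose Ch2 solution is an LTP-blocking inhibitor."""
    cfg = ControllerConfig(PerfusionLine.SLOW0, mode="valvebits", n_channels=8,
                           port="Port1")
    if system == "preflush":
        cfg = ControllerConfig(PerfusionLine.SLOW0, mode="valvebits",
                               n_channels=4, valves_per_channel=2, port="Port1")
    segments = [TubingSegment(30.0, 0.8, "reservoir_to_junction"),
                TubingSegment(9.0, 0.8, "junction_to_manifold")]
    return RigConfig(
        controllers={PerfusionLine.SLOW0: cfg},
        transport={PerfusionLine.SLOW0: TransportModel(
            segments=segments, flow_rate_ml_min=2.0, chamber_volume_ml=1.0,
            system=system)},
        sweep_defs=slice_sweep_defs(),
        inter_sweep_interval_s=30.0,
        biology=SliceModel(noise_sd=noise_sd, rng_seed=seed),
    )


def circular_baseline_script() -> ProtocolScript:
    return parse_protocol(CIRCULAR_BASELINE, name="circular_baseline.proto")


def circular_runonce_script() -> ProtocolScript:
    return parse_protocol(CIRCULAR_RUNONCE, name="circular_runonce.proto")


def sequential_ltp_script() -> ProtocolScript:
    return parse_protocol(SEQUENTIAL_LTP, name="sequential_ltp.proto")


def sequential_ltp_controls(baseline_sweeps: int = 3) -> list[ControlEvent]:
    """Operator unchecks the baseline loop after a stable baseline."""
    return [ControlEvent("uncheck_loop", after_sweep=baseline_sweeps,
                         loop_index=0)]


def slice_ltp_script() -> ProtocolScript:
    return parse_protocol(SLICE_LTP_PERFUSION, name="slice_ltp_perfusion.proto")


def slice_ltp_controls(baseline_sweeps: int = 3) -> list[ControlEvent]:
    return [ControlEvent("uncheck_loop", after_sweep=baseline_sweeps,
                         loop_index=0)]


# ---------------------------------------------------------------------------
# single-line patch-clamp experiments


def _patch_sweep_defs(step1_channels: dict[str, int],
                      apply_ms: float = 1000.0) -> dict[str, SweepDef]:
    """Three-epoch perfusion sweeps: hold / apply channel / hold."""
    defs = {}
    for name, ch in step1_channels.items():
        defs[name] = SweepDef(
            name, duration_ms=3000.0, sample_rate_hz=2000.0,
            ic1_epochs=(Epoch(1000.0, -1.0), Epoch(apply_ms, float(ch)),
                        Epoch(3000.0 - 1000.0 - apply_ms, -1.0)))
    return defs


def patch_rig_8ch(noise_sd: float = 0.0, seed: int = 0) -> RigConfig:
    """8-channel, 1 V/channel analog controller on the Fast0 line: four
    antagonist-only channels (1–4, tightly bound) and four agonist channels
    (5–8)."""
    solutions = {ch: (0.0, ANTAGONIST_UM[ch - 1]) for ch in range(1, 5)}
    solutions.update({ch + 4: (AGONIST_UM[ch - 1], 0.0) for ch in range(1, 5)})
    return RigConfig(
        controllers={PerfusionLine.FAST0: ControllerConfig(
            PerfusionLine.FAST0, mode="analog", n_channels=8,
            volts_per_channel=1.0, valve_switch_time_ms=4.0)},
        sweep_defs=_patch_sweep_defs(
            {"P0sweep": 5, "P1sweep": 6, "T0sweep": 7, "T1sweep": 8}),
        ic1_line=PerfusionLine.FAST0,
        inter_sweep_interval_s=10.0,
        biology=PatchModel(noise_sd=noise_sd, rng_seed=seed),
        channel_solution_um=solutions,
    )


FAST_SINGLE_LINE = """\
# tightly bound antagonist: perfuse each antagonist channel, then apply the
# four agonist channels during the four sweeps
MainProtocol
  Perfuse Fast0 1
  Delay 10
  P0sweep
  P1sweep
  T0sweep
  T1sweep
  Perfuse Fast0 2
  P0sweep
  P1sweep
  T0sweep
  T1sweep
  Perfuse Fast0 3
  P0sweep
  P1sweep
  T0sweep
  T1sweep
  Perfuse Fast0 4
  P0sweep
  P1sweep
  T0sweep
  T1sweep
EndProtocol

[labels]
Fast0 1 = Antagonist 1
Fast0 2 = Antagonist 2
Fast0 3 = Antagonist 3
Fast0 4 = Antagonist 4
Fast0 5 = Agonist 1
Fast0 6 = Agonist 2
Fast0 7 = Agonist 3
Fast0 8 = Agonist 4
"""


def fast_single_line_script() -> ProtocolScript:
    return parse_protocol(FAST_SINGLE_LINE, name="fast_single_line.proto")


def patch_rig_16ch(noise_sd: float = 0.0, seed: int = 0) -> RigConfig:
    """16-channel, 0.5 V/channel analog controller for the loosely bound
    antagonist design: channels 1–3 antagonist-only, 4–15 the twelve
    agonist+antagonist mixes."""
    solutions: dict[int, tuple[float, float]] = {}
    for k in range(1, 4):  # antagonist index
        antag = ANTAGONIST_UM[k]
        solutions[k] = (0.0, antag)
        for j in range(1, 5):  # agonist index
            solutions[3 + 4 * (k - 1) + j] = (AGONIST_UM[j - 1], antag)
    return RigConfig(
        controllers={PerfusionLine.FAST0: ControllerConfig(
            PerfusionLine.FAST0, mode="analog", n_channels=16,
            volts_per_channel=0.5, valve_switch_time_ms=4.0)},
        ic1_line=PerfusionLine.FAST0,
        inter_sweep_interval_s=10.0,
        biology=PatchModel(noise_sd=noise_sd, rng_seed=seed),
        channel_solution_um=solutions,
    )


def linked_fast_perfusion_scripts() -> list[tuple[ProtocolScript, bool]]:
    """Three linked protocols, one antagonist concentration each.

    Protocol k continuously perfuses antagonist channel k and momentarily
    applies the four agonist+antagonist channels 4(k−1)+4 … 4(k−1)+7 during
    its four sweeps, three times over; 15 distinct solutions in total.
    Each protocol autostarts the next.
    """
    plans = []
    for k in (1, 2, 3):
        body = f"""\
MainProtocol
  Perfuse Fast0 {k}
  Delay 10
  Loop 3
    P0sweep
    P1sweep
    T0sweep
    T1sweep
  EndLoop
EndProtocol

[labels]
Fast0 {k} = Antagonist {k}
"""
        if k < 3:
            body += f"""
[link]
next = fast_perfusion{k + 1}.proto
autostart = true
"""
        script = parse_protocol(body, name=f"fast_perfusion{k}.proto")
        base = 3 + 4 * (k - 1)
        script.sweep_defs = _patch_sweep_defs(
            {"P0sweep": base + 1, "P1sweep": base + 2,
             "T0sweep": base + 3, "T1sweep": base + 4})
        for j in range(1, 5):
            script.labels[(PerfusionLine.FAST0, base + j)] = \
                f"Antagonist {k} + Agonist {j}"
        plans.append((script, True))
    return plans


# ---------------------------------------------------------------------------
# triple-line stepper experiment

TRIPLE_LINE_STEPPER = """\
# triple-line stepper: Tube0<-Slow0 and Tube2<-Fast1 carry agonists, the
# antagonist flows from Tube1<-Slow1; the Fast0 analog output steps the
# tube assembly during P0 (to Tube0) and P1 (to Tube2) sweeps
MainProtocol
  Perfuse Slow1 1
  Perfuse Fast0 1
  Perfuse Slow0 1
  P0sweep
  Perfuse Slow0 2
  P0sweep
  Perfuse Fast1 1
  P1sweep
  Perfuse Fast1 2
  P1sweep
  Perfuse Slow1 2
  Perfuse Slow0 1
  P0sweep
  Perfuse Slow0 2
  P0sweep
  Perfuse Fast1 1
  P1sweep
  Perfuse Fast1 2
  P1sweep
EndProtocol

[labels]
Slow1 1 = Antag1
Slow1 2 = Antag2
Slow0 1 = Ag1
Slow0 2 = Ag2
Fast1 1 = Ag3
Fast1 2 = Ag4
"""


def stepper_rig() -> RigConfig:
    """Dual-agonist/antagonist triple-line rig: three valve controllers
    (Slow0, Slow1, Fast1) feed side-by-side tubes, and Fast0 drives the
    stepper at 1 V per tube position (channel == tube)."""
    mk = lambda line: ControllerConfig(line, mode="valvebits", n_channels=8)
    return RigConfig(
        controllers={
            PerfusionLine.SLOW0: mk(PerfusionLine.SLOW0),
            PerfusionLine.SLOW1: mk(PerfusionLine.SLOW1),
            PerfusionLine.FAST1: mk(PerfusionLine.FAST1),
            PerfusionLine.FAST0: ControllerConfig(
                PerfusionLine.FAST0, mode="analog", n_channels=2,
                volts_per_channel=1.0, valve_switch_time_ms=1.0),
        },
        sweep_defs={
            # momentary 50 ms step to Tube0 (P0) or Tube2 (P1), else hold
            "P0sweep": SweepDef("P0sweep", duration_ms=300.0,
                                sample_rate_hz=10_000.0,
                                ic1_epochs=(Epoch(100.0, -1.0), Epoch(50.0, 0.0),
                                            Epoch(150.0, -1.0))),
            "P1sweep": SweepDef("P1sweep", duration_ms=300.0,
                                sample_rate_hz=10_000.0,
                                ic1_epochs=(Epoch(100.0, -1.0), Epoch(50.0, 2.0),
                                            Epoch(150.0, -1.0))),
        },
        stepper=StepperConfig(),
        ic1_line=PerfusionLine.FAST0,
        inter_sweep_interval_s=5.0,
    )


def stepper_script() -> ProtocolScript:
    return parse_protocol(TRIPLE_LINE_STEPPER, name="triple_line_stepper.proto")


# ---------------------------------------------------------------------------


def write_example_files(directory: str | Path) -> list[Path]:
    """Write the fixture protocol files (and rig configs) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    texts = {
        "circular_baseline.proto": CIRCULAR_BASELINE,
        "circular_runonce.proto": CIRCULAR_RUNONCE,
        "sequential_ltp.proto": SEQUENTIAL_LTP,
        "slice_ltp_perfusion.proto": SLICE_LTP_PERFUSION,
        "fast_single_line.proto": FAST_SINGLE_LINE,
        "triple_line_stepper.proto": TRIPLE_LINE_STEPPER,
    }
    for script, _ in linked_fast_perfusion_scripts():
        from .protocol_model import serialize_protocol

        texts[script.name] = serialize_protocol(script)
    for name, text in texts.items():
        path = directory / name
        path.write_text(text)
        written.append(path)
    for name, rig in (("slice_rig.yaml", slice_rig()),
                      ("patch_rig_8ch.yaml", patch_rig_8ch()),
                      ("patch_rig_16ch.yaml", patch_rig_16ch()),
                      ("stepper_rig.yaml", stepper_rig())):
        path = directory / name
        rig.to_yaml(path)
        written.append(path)
    controls = directory / "slice_ltp_controls.csv"
    controls.write_text("# uncheck the baseline loop after 3 sweeps\n"
                        "sweep=3,uncheck_loop,loop=0\n")
    written.append(controls)
    return written
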
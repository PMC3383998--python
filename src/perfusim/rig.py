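"""Rig configuration: controllers, hydraulics, sweep definitions, biology.

A :class:`RigConfig` bundles everything the executor needs besides the
protocol script itself: one controller (and optionally a transport geometry)
per perfusion line, the named sweep definitions, an optional stepper, and an
optional biology model (slice or patch) for synthetic acquisition.  Configs
round-trip through YAML files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .perfusion import (
    ControllerConfig,
    PerfusionLine,
    StepperConfig,
    TubingSegment,
)
from .sweep_engine import CommandStep, Epoch, PulseTrain, SweepDef
from .virtual_rig import PatchModel, SliceModel, TransportModel


@dataclass
class RigConfig:
    controllers: dict[PerfusionLine, ControllerConfig] = field(default_factory=dict)
    transport: dict[PerfusionLine, TransportModel] = field(default_factory=dict)
    sweep_defs: dict[str, SweepDef] = field(default_factory=dict)
    stepper: StepperConfig | None = None
    ic1_line: PerfusionLine = PerfusionLine.FAST0
    inter_sweep_interval_s: float = 30.0
    # static digital ports are written directly by the host, so slow-line
    # valve actions may lag by up to this much (uniform jitter); Fast-line
    # and in-sweep actions are sweep-clocked and exact
    slow_latency_jitter_ms: float = 0.0
    biology: SliceModel | PatchModel | None = None
    # patch rigs: chamber channel -> (agonist µM, antagonist µM)
    channel_solution_um: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.controllers = {PerfusionLine(k): v for k, v in self.controllers.items()}
        self.transport = {PerfusionLine(k): v for k, v in self.transport.items()}
        if isinstance(self.ic1_line, str):
            self.ic1_line = PerfusionLine(self.ic1_line)
        if not 0 <= self.slow_latency_jitter_ms <= 50:
            raise ValueError("slow-line latency jitter must be within 0..50 ms")

    def controller(self, line: PerfusionLine) -> ControllerConfig | None:
        return self.controllers.get(PerfusionLine(line))

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "controllers": {ln.value: asdict(cfg)
                            for ln, cfg in self.controllers.items()},
            "transport": {ln.value: asdict(tm)
                          for ln, tm in self.transport.items()},
            "sweep_defs": {name: asdict(sd)
                           for name, sd in self.sweep_defs.items()},
            "ic1_line": self.ic1_line.value,
            "inter_sweep_interval_s": self.inter_sweep_interval_s,
            "slow_latency_jitter_ms": self.slow_latency_jitter_ms,
            "channel_solution_um": {ch: list(v) for ch, v
                                    in self.channel_solution_um.items()},
        }
        if self.stepper is not None:
            sd = asdict(self.stepper)
            sd["feeding_line"] = {k: v.value if isinstance(v, PerfusionLine) else v
                                  for k, v in sd["feeding_line"].items()}
            sd["tubes"] = list(sd["tubes"])
            d["stepper"] = sd
        if self.biology is not None:
            kind = "slice" if isinstance(self.biology, SliceModel) else "patch"
            bd = {f.name: getattr(self.biology, f.name)
                  for f in fields(self.biology)}
            if kind == "slice":
                bd["inhibitor_channels"] = sorted(bd["inhibitor_channels"])
            d["biology"] = {"kind": kind, **bd}
        # enums/tuples -> plain YAML types
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RigConfig":
        controllers = {
            PerfusionLine(ln): ControllerConfig(**cfg)
            for ln, cfg in d.get("controllers", {}).items()
        }
        transport = {}
        for ln, tm in d.get("transport", {}).items():
            segs = [TubingSegment(**s) for s in tm.get("segments", [])]
            transport[PerfusionLine(ln)] = TransportModel(
                segments=segs,
                flow_rate_ml_min=tm.get("flow_rate_ml_min", 2.0),
                chamber_volume_ml=tm.get("chamber_volume_ml", 1.0),
                system=tm.get("system", "standard"),
            )
        sweep_defs = {name: sweep_def_from_dict(sd)
                      for name, sd in d.get("sweep_defs", {}).items()}
        stepper = None
        if "stepper" in d:
            sd = dict(d["stepper"])
            sd["tubes"] = tuple(sd.get("tubes", (0, 1, 2)))
            sd["feeding_line"] = {int(k): PerfusionLine(v) for k, v
                                  in sd.get("feeding_line", {}).items()}
            stepper = StepperConfig(**sd)
        biology = None
        if "biology" in d:
            bd = dict(d["biology"])
            kind = bd.pop("kind")
            if kind == "slice":
                bd["inhibitor_channels"] = frozenset(bd.get("inhibitor_channels", ()))
                biology = SliceModel(**bd)
            else:
                biology = PatchModel(**bd)
        return cls(
            controllers=controllers,
            transport=transport,
            sweep_defs=sweep_defs,
            stepper=stepper,
            ic1_line=PerfusionLine(d.get("ic1_line", "Fast0")),
            inter_sweep_interval_s=d.get("inter_sweep_interval_s", 30.0),
            slow_latency_jitter_ms=d.get("slow_latency_jitter_ms", 0.0),
            biology=biology,
            channel_solution_um={int(k): tuple(v) for k, v
                                 in d.get("channel_solution_um", {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RigConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def sweep_def_from_dict(sd: dict) -> SweepDef:
    sd = dict(sd)
    for key in ("s0_train", "s1_train"):
        if sd.get(key) is not None:
            sd[key] = PulseTrain(**sd[key])
    if sd.get("ic0_steps"):
        sd["ic0_steps"] = [CommandStep(**s) for s in sd["ic0_steps"]]
    if sd.get("ic1_epochs") is not None:
        sd["ic1_epochs"] = tuple(Epoch(**e) for e in sd["ic1_epochs"])
    return SweepDef(**sd)


def _plainify(obj):
    """Recursively convert enums/tuples/frozensets to YAML-safe types."""
    import enum

    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {_plainify(k): _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    return obj
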
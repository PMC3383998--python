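"""Virtual rig: plug-flow solution transport and synthetic responses.

This module is the hardware-free stand-in for the hydraulics and the
biology.  Transport is plug flow: when a perfusion line is switched on, the
stale contents of its dead volume (reservoir→manifold for a standard system,
T/Y-junction→manifold when the line was pre-flushed or continuously flowing
to waste) arrive at the chamber first, over ``volume / flow_rate`` seconds,
followed by fresh solution.  The chamber is a single well-mixed compartment
with turnover ``flow / chamber_volume``.

Responses are deliberately simple, fully parameterized models that make
every analysis path exercisable:

* slice fEPSP — a stereotyped fiber volley + negative synaptic deflection
  per stimulus pulse, whose initial slope is the pathway slope; a train
  potentiates the pathway by ``ltp_factor`` unless an inhibitor solution is
  present in the chamber above a blocking threshold;
* patch-clamp agonist response — Hill activation with a competitive
  (Schild) antagonist shift of EC50, relaxing with on/off time constants;
* seal test — the RC transient of a voltage step through the electrode
  series resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import Trace
from .perfusion import PerfusionError, TubingSegment, dead_volume
from .sweep_engine import SweepDef

# fEPSP template shape (ms, relative to stimulus pulse)
_SYNAPTIC_DELAY_MS = 2.0
_TAU_RISE_MS = 0.8
_TAU_DECAY_MS = 8.0
_FV_DELAY_MS = 0.7
_FV_SIGMA_MS = 0.25
# slope measurement window relative to the stimulus pulse; synthesis
# calibrates the template so the OLS slope over this window is exactly the
# pathway slope
SLOPE_WINDOW_MS = (_SYNAPTIC_DELAY_MS + 0.5, _SYNAPTIC_DELAY_MS + 2.5)


@dataclass
class TransportModel:
    """Hydraulic geometry of one perfusion line feeding the chamber."""

    segments: list[TubingSegment] = field(default_factory=lambda: [
        TubingSegment(30.0, 0.8, "reservoir_to_junction"),
        TubingSegment(9.0, 0.8, "junction_to_manifold"),
    ])
    flow_rate_ml_min: float = 2.0
    chamber_volume_ml: float = 1.0
    system: str = "standard"  # standard | preflush | flow_to_waste

    def __post_init__(self) -> None:
        if self.system not in ("standard", "preflush", "flow_to_waste"):
            raise PerfusionError(f"unknown perfusion system {self.system!r}")
        if self.flow_rate_ml_min <= 0 or self.chamber_volume_ml <= 0:
            raise PerfusionError("flow rate and chamber volume must be positive")

    def volume(self, role: str) -> float:
        return sum(dead_volume(s) for s in self.segments if s.role == role)

    @property
    def stale_bolus_ml(self) -> float:
        """Stale volume delivered to the manifold on a switch.

        A standard system delivers everything upstream of the chamber valve
        (reservoir→manifold); pre-flush and continuous-flow-to-waste systems
        have already cleared the reservoir→junction stretch, so only the
        junction→manifold dead volume is stale — smaller, but never zero for
        real tubing.
        """
        jm = self.volume("junction_to_manifold")
        if self.system == "standard":
            return self.volume("reservoir_to_junction") + jm
        return jm

    @property
    def flow_ml_s(self) -> float:
        return self.flow_rate_ml_min / 60.0

    @property
    def stale_bolus_duration_s(self) -> float:
        return self.stale_bolus_ml / self.flow_ml_s


@dataclass
class ChamberSeries:
    """Chamber composition over time: per-solution concentration (fraction
    of chamber volume, keyed by channel) plus the stale-solution fraction."""

    time_s: np.ndarray
    conc: dict[int, np.ndarray]
    stale: np.ndarray

    def at(self, channel: int, t: float) -> float:
        if channel not in self.conc:
            return 0.0
        i = int(np.searchsorted(self.time_s, t, side="right")) - 1
        return float(self.conc[channel][max(i, 0)])


def advance_transport(model: TransportModel,
                      switches: list[tuple[float, int]],
                      dt_s: float,
                      t_end_s: float | None = None) -> ChamberSeries:
    """Integrate chamber composition given a channel-selection timeline.

    ``switches`` is the time-ordered list of (time_s, channel) selections of
    this line (channel 0 = off, flow stopped).  On each switch to a nonzero
    channel the stale bolus arrives first (plug flow), then fresh solution;
    the chamber mixes with turnover flow/chamber_volume.  Exact exponential
    stepping is used within each constant-inflow interval, so solute mass is
    conserved to numerical precision.
    """
    if dt_s <= 0:
        raise PerfusionError("dt must be positive")
    switches = sorted(switches)
    if t_end_s is None:
        t_end_s = (switches[-1][0] if switches else 0.0) + 60.0
    n = int(np.ceil(t_end_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    channels = sorted({ch for _, ch in switches if ch != 0})
    conc = {ch: np.zeros(n) for ch in channels}
    stale = np.zeros(n)

    # inflow composition per sample: active channel and staleness
    active = np.zeros(n, dtype=int)
    fresh_at = np.full(n, np.inf)
    for t_sw, ch in switches:
        i0 = int(np.ceil(t_sw / dt_s - 1e-12))
        active[i0:] = ch
        if ch != 0:
            fresh_at[i0:] = t_sw + model.stale_bolus_duration_s
    is_stale = t < fresh_at

    k = model.flow_ml_s / model.chamber_volume_ml  # turnover rate, 1/s
    decay = np.exp(-k * dt_s)
    for i in range(1, n):
        ch = active[i - 1]
        flowing = ch != 0
        f = decay if flowing else 1.0
        for c in channels:
            inflow = 1.0 if c == ch else 0.0
            conc[c][i] = inflow + (conc[c][i - 1] - inflow) * f if flowing \
                else conc[c][i - 1]
        s_in = 1.0 if (flowing and is_stale[i - 1]) else 0.0
        stale[i] = s_in + (stale[i - 1] - s_in) * f if flowing else stale[i - 1]
    return ChamberSeries(t, conc, stale)


# ---------------------------------------------------------------------------
# slice biology


@dataclass
class SliceModel:
    """Synthetic hippocampal-slice pathway driven by chamber composition.

    ``baseline_slope`` is the signed initial fEPSP slope (mV/ms, negative
    for the usual downward field potential).  A stimulus train potentiates
    the stimulated pathway by ``ltp_factor`` unless any channel in
    ``inhibitor_channels`` is present in the chamber at or above
    ``inhibitor_block_threshold`` (volume fraction) at train time.
    """

    baseline_slope: float = -0.15
    ltp_factor: float = 1.5
    inhibitor_channels: frozenset[int] = frozenset({2})
    inhibitor_block_threshold: float = 0.5
    noise_sd: float = 0.0
    rng_seed: int = 0
    train_pulse_threshold: int = 10  # >= this many pulses counts as a train

    def __post_init__(self) -> None:
        if self.ltp_factor < 1:
            raise PerfusionError("ltp_factor must be >= 1")
        if not 0 <= self.inhibitor_block_threshold <= 1:
            raise PerfusionError("block threshold must be in [0, 1]")
        self.pathway_gain: dict[str, float] = {"S0": 1.0, "S1": 1.0}
        self._rng = np.random.default_rng(self.rng_seed)

    def reset(self) -> None:
        self.pathway_gain = {"S0": 1.0, "S1": 1.0}
        self._rng = np.random.default_rng(self.rng_seed)


def _fepsp_template(dt_ms: float, span_ms: float) -> np.ndarray:
    """Unit fEPSP shape: small positive fiber volley then a negative
    difference-of-exponentials synaptic deflection (peak scaled to −1)."""
    t = np.arange(int(round(span_ms / dt_ms))) * dt_ms
    syn = np.where(
        t >= _SYNAPTIC_DELAY_MS,
        np.exp(-(t - _SYNAPTIC_DELAY_MS) / _TAU_DECAY_MS)
        - np.exp(-(t - _SYNAPTIC_DELAY_MS) / _TAU_RISE_MS),
        0.0,
    )
    peak = syn.max()
    syn = -syn / peak if peak > 0 else syn
    fv = 0.15 * np.exp(-((t - _FV_DELAY_MS) ** 2) / (2 * _FV_SIGMA_MS**2))
    return fv + syn


def _template_slope(dt_ms: float) -> float:
    """OLS slope of the unit template over the standard slope window."""
    tpl = _fepsp_template(dt_ms, 40.0)
    tr = Trace(tpl, dt_ms)
    from .analysis import measure_slope

    return measure_slope(tr, SLOPE_WINDOW_MS)


def synth_field_sweep(slc: SliceModel, sweep: SweepDef,
                      inhibitor_conc: float, pathway: str = "S0") -> Trace:
    """Synthesize the extracellular (AD0) trace for one sweep and apply the
    plasticity rule if the sweep is an induction train."""
    train = sweep.s0_train if pathway == "S0" else sweep.s1_train
    if train is None or train.pulse_count < 1:
        raise PerfusionError("field sweep needs at least one stimulus pulse")
    dt_ms = 1000.0 / sweep.sample_rate_hz
    n = sweep.n_samples
    y = np.zeros(n)
    slope = slc.baseline_slope * slc.pathway_gain[pathway]
    unit_slope = _template_slope(dt_ms)
    tpl = _fepsp_template(dt_ms, 40.0) * (slope / unit_slope)
    for t0 in train.edge_times_ms():
        i0 = int(round(t0 / dt_ms))
        m = min(tpl.size, n - i0)
        if m > 0:
            y[i0:i0 + m] += tpl[:m]
    if slc.noise_sd > 0:
        y += slc._rng.normal(0.0, slc.noise_sd, size=n)
    if train.pulse_count >= slc.train_pulse_threshold:
        if inhibitor_conc < slc.inhibitor_block_threshold:
            slc.pathway_gain[pathway] *= slc.ltp_factor
    return Trace(y, dt_ms, units="mV")


# ---------------------------------------------------------------------------
# patch-clamp biology


@dataclass
class PatchModel:
    """Synthetic voltage-clamped cell with Hill/Schild pharmacology.

    Steady-state agonist response Emax·cʰ/(cʰ + (EC50·(1 + B/Ki))ʰ) — a
    competitive antagonist at concentration B shifts the apparent EC50 by
    (1 + B/Ki) — relaxing with ``tau_on_ms``/``tau_off_ms``.  Passive
    properties (Rs, Rin, Cm) shape the seal-test transient.
    """

    emax_pa: float = 500.0
    ec50_um: float = 10.0
    hill_h: float = 1.0
    ki_um: float = 5.0
    tau_on_ms: float = 20.0
    tau_off_ms: float = 50.0
    rin_mohm: float = 100.0
    rs_mohm: float = 10.0
    cm_pf: float = 33.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ec50_um", "ki_um", "tau_on_ms", "tau_off_ms",
                     "rin_mohm", "cm_pf"):
            if getattr(self, name) <= 0:
                raise PerfusionError(f"{name} must be positive")
        if self.rs_mohm < 0:
            raise PerfusionError("rs_mohm must be non-negative")
        self._rng = np.random.default_rng(self.rng_seed)

    def steady_state(self, agonist_um: float, antagonist_um: float = 0.0) -> float:
        if agonist_um <= 0:
            return 0.0
        ec50 = self.ec50_um * (1.0 + antagonist_um / self.ki_um)
        ch = agonist_um ** self.hill_h
        return self.emax_pa * ch / (ch + ec50 ** self.hill_h)


def synth_patch_sweep(patch: PatchModel, agonist_um: np.ndarray,
                      antagonist_um: np.ndarray | float, dt_ms: float) -> Trace:
    """Agonist-evoked current (pA) for per-sample concentration series."""
    agonist_um = np.asarray(agonist_um, dtype=float)
    n = agonist_um.size
    if np.isscalar(antagonist_um) or np.ndim(antagonist_um) == 0:
        antagonist_um = np.full(n, float(antagonist_um))
    else:
        antagonist_um = np.asarray(antagonist_um, dtype=float)
        if antagonist_um.size != n:
            raise PerfusionError("concentration series lengths differ")
    y = np.zeros(n)
    r = 0.0
    a_on = 1.0 - np.exp(-dt_ms / patch.tau_on_ms)
    a_off = 1.0 - np.exp(-dt_ms / patch.tau_off_ms)
    for i in range(n):
        target = patch.steady_state(agonist_um[i], antagonist_um[i])
        r += (target - r) * (a_on if target > r else a_off)
        y[i] = r
    if patch.noise_sd > 0:
        y += patch._rng.normal(0.0, patch.noise_sd, size=n)
    return Trace(y, dt_ms, units="pA")


def synth_seal_test(patch: PatchModel, step_mv: float, duration_ms: float,
                    dt_ms: float = 0.01, n_exp: int = 1,
                    tau2_factor: float = 5.0, a2_fraction: float = 0.3) -> Trace:
    """RC current transient (pA) of a voltage step through Rs.

    Peak = ΔV/Rs decaying with τ = Rs·Cm toward the steady state
    ΔV/(Rs + Rin).  With ``n_exp=2`` a second, slower component
    (τ₂ = tau2_factor·τ, carrying ``a2_fraction`` of the transient) is
    added, mimicking imperfect capacitance compensation.
    """
    if step_mv <= 0 or duration_ms <= 0:
        raise PerfusionError("seal test needs positive step and duration")
    if patch.rs_mohm <= 0:
        raise PerfusionError("Rs -> 0: peak current unbounded")
    t = np.arange(int(round(duration_ms / dt_ms))) * dt_ms
    i_peak = 1000.0 * step_mv / patch.rs_mohm  # mV/MΩ = nA -> pA
    i_ss = 1000.0 * step_mv / (patch.rs_mohm + patch.rin_mohm)
    tau_ms = patch.rs_mohm * patch.cm_pf / 1000.0  # MΩ·pF = µs
    transient = i_peak - i_ss
    if n_exp == 1:
        y = i_ss + transient * np.exp(-t / tau_ms)
    else:
        y = (i_ss
             + (1 - a2_fraction) * transient * np.exp(-t / tau_ms)
             + a2_fraction * transient * np.exp(-t / (tau2_factor * tau_ms)))
    if patch.noise_sd > 0:
        y += patch._rng.normal(0.0, patch.noise_sd, size=t.size)
    return Trace(y, dt_ms, units="pA")
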
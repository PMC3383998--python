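"""Online measurement battery computed per acquired sweep.

Measurements mirror the standard extracellular/patch-clamp repertoire: fEPSP
initial slope and maximum slope, peak amplitude, population-spike amplitude,
average amplitude, area, rise time (10–90%), decay time (to 37% of peak),
half-amplitude duration, cell input resistance and patch-electrode series
resistance (single- or double-exponential transient fit).

Conventions (config-overridable through :class:`MeasurementSpec` options):
slope is an ordinary least-squares fit over the window; peak is the extreme
deviation from the baseline-window mean, signed; area is the trapezoidal
integral of the baseline-subtracted trace; the population-spike amplitude is
the vertical distance from the spike trough to the chord joining the two
flanking positive peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class MeasurementError(ValueError):
    """Raised when a measurement is undefined on the given trace."""


@dataclass
class Trace:
    """Uniformly sampled acquisition data (mV for field/voltage, pA for
    current)."""

    samples: np.ndarray
    dt_ms: float
    t0_ms: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise MeasurementError("trace needs >= 2 uniformly sampled points")
        if self.dt_ms <= 0:
            raise MeasurementError("sampling interval must be positive")

    @property
    def time_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) * self.dt_ms

    @property
    def end_ms(self) -> float:
        return self.t0_ms + (self.samples.size - 1) * self.dt_ms

    def window_slice(self, window: tuple[float, float]) -> slice:
        t1, t2 = window
        if t1 >= t2:
            raise MeasurementError(f"window ({t1}, {t2}) is empty")
        if t1 < self.t0_ms - 1e-9 or t2 > self.end_ms + 1e-9:
            raise MeasurementError(
                f"window ({t1}, {t2}) ms outside trace "
                f"[{self.t0_ms}, {self.end_ms}] ms")
        i1 = int(np.ceil((t1 - self.t0_ms) / self.dt_ms - 1e-9))
        i2 = int(np.floor((t2 - self.t0_ms) / self.dt_ms + 1e-9)) + 1
        return slice(max(i1, 0), min(i2, self.samples.size))


@dataclass
class MeasurementSpec:
    kind: str
    window: tuple[float, float]
    baseline_window: tuple[float, float] | None = None
    options: dict = field(default_factory=dict)


BASIC_KINDS = ("peak_amplitude", "average_amplitude", "area", "rise_time",
               "decay_time", "duration", "pop_spike")


def _baseline(trace: Trace, baseline_window) -> float:
    if baseline_window is None:
        return 0.0
    return float(np.mean(trace.samples[trace.window_slice(baseline_window)]))


def measure_slope(trace: Trace, window: tuple[float, float]) -> float:
    """OLS slope (units/ms) over a time window."""
    sl = trace.window_slice(window)
    y = trace.samples[sl]
    if y.size < 3:
        raise MeasurementError("slope needs >= 3 samples in the window")
    x = trace.time_ms[sl]
    return float(np.polyfit(x, y, 1)[0])


def measure_max_slope(trace: Trace, window: tuple[float, float],
                      subwindow_ms: float) -> float:
    """Maximum sliding-window OLS slope (1-sample stride) within ``window``."""
    sl = trace.window_slice(window)
    y = trace.samples[sl]
    m = int(round(subwindow_ms / trace.dt_ms)) + 1
    if m < 3:
        raise MeasurementError("max-slope subwindow spans < 3 samples")
    if m > y.size:
        raise MeasurementError("subwindow wider than the window")
    # closed-form OLS slope on uniform x: correlate with a centered ramp
    k = np.arange(m) - (m - 1) / 2.0
    denom = np.sum(k**2) * trace.dt_ms
    slopes = np.correlate(y, k, mode="valid") / denom
    return float(slopes.max())


def measure_basic(trace: Trace, spec: MeasurementSpec) -> float:
    """Peak/average/area/rise/decay/duration/pop-spike measurements."""
    if spec.kind not in BASIC_KINDS:
        raise MeasurementError(f"unknown basic measurement {spec.kind!r}")
    base = _baseline(trace, spec.baseline_window)
    sl = trace.window_slice(spec.window)
    dev = trace.samples[sl] - base
    t = trace.time_ms[sl]

    if spec.kind == "average_amplitude":
        return float(dev.mean())
    if spec.kind == "area":
        return float(np.trapezoid(dev, dx=trace.dt_ms))
    if spec.kind == "pop_spike":
        return _pop_spike(dev)

    i_ext = int(np.argmax(np.abs(dev)))
    peak = dev[i_ext]
    if peak == 0:
        raise MeasurementError("flat trace: no identifiable peak")
    if spec.kind == "peak_amplitude":
        return float(peak)

    mag = dev * np.sign(peak)  # flip so the peak is positive
    pk = abs(peak)

    def first_crossing(seg_t, seg_y, level, rising):
        """Linear-interpolated time where seg_y first crosses level."""
        above = seg_y >= level if rising else seg_y <= level
        idx = np.flatnonzero(above)
        if idx.size == 0:
            raise MeasurementError("trace never crosses measurement level")
        i = idx[0]
        if i == 0:
            return seg_t[0]
        y0, y1 = seg_y[i - 1], seg_y[i]
        frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
        return seg_t[i - 1] + frac * (seg_t[i] - seg_t[i - 1])

    if spec.kind == "rise_time":
        rise_t, rise_y = t[: i_ext + 1], mag[: i_ext + 1]
        t10 = first_crossing(rise_t, rise_y, 0.10 * pk, rising=True)
        t90 = first_crossing(rise_t, rise_y, 0.90 * pk, rising=True)
        return float(t90 - t10)
    if spec.kind == "decay_time":
        frac = spec.options.get("decay_fraction", 0.37)
        fall_t, fall_y = t[i_ext:], mag[i_ext:]
        t_d = first_crossing(fall_t, fall_y, frac * pk, rising=False)
        return float(t_d - t[i_ext])
    if spec.kind == "duration":
        half = 0.5 * pk
        t_up = first_crossing(t[: i_ext + 1], mag[: i_ext + 1], half, rising=True)
        t_dn = first_crossing(t[i_ext:], mag[i_ext:], half, rising=False)
        return float(t_dn - t_up)
    raise MeasurementError(spec.kind)


def _pop_spike(dev: np.ndarray) -> float:
    """Trough-to-chord population-spike amplitude.

    Finds the deepest trough, the highest point on each side of it, and
    returns the vertical distance from the trough to the straight line
    joining those two flanking positive peaks.
    """
    i_tr = int(np.argmin(dev))
    if i_tr == 0 or i_tr == dev.size - 1:
        raise MeasurementError("population-spike trough lacks flanking peaks")
    i_l = int(np.argmax(dev[:i_tr]))
    i_r = i_tr + int(np.argmax(dev[i_tr:]))
    if dev[i_l] <= dev[i_tr] or dev[i_r] <= dev[i_tr]:
        raise MeasurementError("no positive flanking peaks around trough")
    frac = (i_tr - i_l) / (i_r - i_l)
    chord = dev[i_l] + frac * (dev[i_r] - dev[i_l])
    return float(chord - dev[i_tr])


def input_resistance(trace: Trace, step: float,
                     window: tuple[float, float],
                     baseline_window: tuple[float, float] | None = None) -> float:
    """Steady-state input resistance in MΩ from a test step.

    For a voltage trace (mV) ``step`` is the injected current in pA and the
    result is ΔV/ΔI; for a current trace (pA) ``step`` is the command step
    in mV and the result is ΔV/ΔI with ΔI the steady-state current
    deflection (the total resistance in series with the electrode).
    """
    if step == 0:
        raise MeasurementError("zero test step")
    base = _baseline(trace, baseline_window)
    deflection = float(np.mean(trace.samples[trace.window_slice(window)])) - base
    if trace.units == "pA":
        if deflection == 0:
            raise MeasurementError("zero steady-state current deflection")
        return 1000.0 * step / deflection  # mV / pA -> MΩ
    return 1000.0 * deflection / step  # mV / pA -> MΩ


def series_resistance_fit(trace: Trace, step_mv: float, n_exp: int = 1
                          ) -> tuple[float, tuple[float, ...], float]:
    """Series resistance from the capacitive transient of a voltage step.

    Fits I(t) = I_ss + Σᵢ Aᵢ·exp(−(t−t₀)/τᵢ) from the transient peak and
    back-extrapolates to the step onset: Rs = step / I_peak with
    I_peak = I_ss + ΣAᵢ.  Returns (Rs in MΩ, fitted τ in ms, RMS residual).
    Time constants are bounded to [0.01 ms, 10 × the fitted span].
    """
    if n_exp not in (1, 2):
        raise MeasurementError("n_exp must be 1 or 2")
    y = trace.samples
    i_ss = float(np.mean(y[-max(3, y.size // 10):]))
    i_pk = int(np.argmax(np.abs(y - i_ss)))
    peak_dev = y[i_pk] - i_ss
    span = np.abs(y - i_ss).max()
    if span < 1e-12 or abs(peak_dev) < 0.05 * span + 1e-12:
        raise MeasurementError("no capacitive transient above the noise floor")
    t = (np.arange(y.size - i_pk)) * trace.dt_ms
    yy = y[i_pk:]
    tau_hi = 10.0 * t[-1]

    # seed from a log-linear fit of the decaying tail
    dev = (yy - i_ss) / np.sign(peak_dev)
    pos = dev > max(dev.max() * 1e-4, 1e-12)
    idx = np.flatnonzero(pos)
    if idx.size < 3:
        raise MeasurementError("transient too short to fit")
    coef = np.polyfit(t[idx], np.log(dev[idx]), 1)
    tau0 = float(np.clip(-1.0 / coef[0] if coef[0] < 0 else t[-1] / 3,
                         0.01, tau_hi))
    a0 = float(np.exp(coef[1]) * np.sign(peak_dev))

    if n_exp == 1:
        def model(tt, a, tau, c):
            return c + a * np.exp(-tt / tau)
        p0 = (a0, tau0, i_ss)
        lo = (-np.inf, 0.01, -np.inf)
        hi = (np.inf, tau_hi, np.inf)
    else:
        def model(tt, a1, tau1, a2, tau2, c):
            return c + a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)
        p0 = (0.7 * a0, max(tau0 / 4, 0.011), 0.3 * a0,
              min(tau0 * 2, tau_hi * 0.9), i_ss)
        lo = (-np.inf, 0.01, -np.inf, 0.01, -np.inf)
        hi = (np.inf, tau_hi, np.inf, tau_hi, np.inf)

    try:
        popt, _ = curve_fit(model, t, yy, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        resid = float(np.sqrt(np.mean((model(t, *p0) - yy) ** 2)))
        raise MeasurementError(
            f"series-resistance fit did not converge (seed residual {resid:.3g})"
        ) from err
    resid = float(np.sqrt(np.mean((model(t, *popt) - yy) ** 2)))
    if n_exp == 1:
        amps, taus, c = (popt[0],), (float(popt[1]),), popt[2]
    else:
        amps, taus, c = (popt[0], popt[2]), (float(popt[1]), float(popt[3])), popt[4]
    i_peak = c + sum(amps)
    if i_peak == 0:
        raise MeasurementError("back-extrapolated peak current is zero")
    rs = 1000.0 * step_mv / i_peak  # mV/pA -> MΩ
    return float(rs), tuple(sorted(taus)), resid


def measure(trace: Trace, spec: MeasurementSpec) -> float:
    """Dispatch a :class:`MeasurementSpec` to the right routine."""
    if spec.kind == "slope":
        return measure_slope(trace, spec.window)
    if spec.kind == "max_slope":
        return measure_max_slope(trace, spec.window,
                                 spec.options.get("subwindow_ms", 1.0))
    if spec.kind in BASIC_KINDS:
        return measure_basic(trace, spec)
    if spec.kind == "input_resistance":
        return input_resistance(trace, spec.options["step"], spec.window,
                                spec.baseline_window)
    if spec.kind == "series_resistance":
        rs, _, _ = series_resistance_fit(trace, spec.options["step_mV"],
                                         spec.options.get("n_exponentials", 1))
        return rs
    raise MeasurementError(f"unknown measurement kind {spec.kind!r}")
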
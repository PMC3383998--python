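"""Per-sweep measurement battery: slopes, amplitudes, kinetics, resistances."""

import numpy as np
import pytest

from perfusim.analysis import (
    MeasurementError,
    MeasurementSpec,
    Trace,
    input_resistance,
    measure,
    measure_basic,
    measure_max_slope,
    measure_slope,
    series_resistance_fit,
)
from perfusim.virtual_rig import PatchModel, synth_seal_test


def line_trace(slope, n=100, dt=0.1, intercept=0.0):
    return Trace(intercept + slope * np.arange(n) * dt, dt)


class TestSlope:
    def test_exact_line(self):
        assert measure_slope(line_trace(2.0), (0.0, 9.9)) == pytest.approx(2.0)

    def test_constant_trace(self):
        assert measure_slope(Trace(np.ones(50), 0.1), (0.0, 4.9)) == pytest.approx(0.0)

    def test_noisy_line_within_ols_standard_error(self):
        # oracle: SE(b) = sd / sqrt(sum((x - xbar)^2))
        rng = np.random.default_rng(7)
        n, dt, s, sd = 100, 0.1, 1.7, 0.1
        x = np.arange(n) * dt
        tr = Trace(s * x + rng.normal(0, sd, n), dt)
        se = sd / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(measure_slope(tr, (0.0, x[-1])) - s) < 3 * se

    def test_window_outside_trace(self):
        with pytest.raises(MeasurementError):
            measure_slope(line_trace(1.0), (5.0, 50.0))


class TestMaxSlope:
    def test_monotone_line_equals_slope(self):
        tr = line_trace(1.5)
        w = (0.0, 9.9)
        assert measure_max_slope(tr, w, 1.0) == pytest.approx(
            measure_slope(tr, w))

    def test_piecewise_steep_middle_matches_brute_force(self):
        dt = 0.1
        y = np.concatenate([np.full(30, 0.0),
                            np.linspace(0, 5, 30),
                            np.full(30, 5.0)])
        tr = Trace(y, dt)
        sub = 1.0
        m = int(round(sub / dt)) + 1
        brute = max(
            np.polyfit(np.arange(m) * dt, y[i:i + m], 1)[0]
            for i in range(y.size - m + 1))
        got = measure_max_slope(tr, (0.0, (y.size - 1) * dt), sub)
        assert got == pytest.approx(brute, rel=1e-9)

    def test_sigmoid_max_near_inflection(self):
        dt = 0.05
        t = np.arange(400) * dt
        y = 1.0 / (1.0 + np.exp(-(t - 10.0)))
        tr = Trace(y, dt)
        got = measure_max_slope(tr, (0.0, t[-1]), 0.5)
        # numeric-derivative oracle: max dy/dt = 0.25 at the inflection
        assert got == pytest.approx(np.gradient(y, dt).max(), rel=0.01)

    def test_max_slope_geq_slope(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tr = Trace(rng.normal(size=80).cumsum(), 0.1)
            w = (0.0, 7.9)
            assert measure_max_slope(tr, w, 1.0) >= measure_slope(tr, w) - 1e-12

    def test_subwindow_too_small(self):
        with pytest.raises(MeasurementError):
            measure_max_slope(line_trace(1.0), (0.0, 9.9), 0.05)


class TestBasicMeasurements:
    def test_square_pulse_closed_forms(self):
        dt, w = 0.1, 3.0
        y = np.zeros(100)
        y[20:20 + int(w / dt)] = 1.0
        tr = Trace(y, dt)
        spec = lambda kind: MeasurementSpec(kind, (0.0, 9.9),
                                            baseline_window=(0.0, 1.5))
        assert measure_basic(tr, spec("peak_amplitude")) == pytest.approx(1.0)
        assert measure_basic(tr, spec("area")) == pytest.approx(w, rel=0.05)
        assert measure_basic(tr, spec("duration")) == pytest.approx(w, abs=2 * dt)

    def test_flat_trace_raises(self):
        tr = Trace(np.zeros(50), 0.1)
        with pytest.raises(MeasurementError):
            measure_basic(tr, MeasurementSpec("peak_amplitude", (0.0, 4.9)))

    def test_rise_and_decay_of_exponential(self):
        dt = 0.01
        t = np.arange(3000) * dt
        tau = 5.0
        y = np.where(t >= 1.0, np.exp(-(t - 1.0) / tau), 0.0)
        y[t < 1.0] = 0.0
        y = np.where(t < 1.0, 0.0, y)
        tr = Trace(y, dt)
        spec = MeasurementSpec("decay_time", (0.0, t[-1]))
        # decay to 37% of an exponential takes ~tau
        assert measure_basic(tr, spec) == pytest.approx(-tau * np.log(0.37),
                                                        rel=0.02)

    def test_pop_spike_chord_geometry(self):
        # two positive humps with a trough dropping `a` below their chord
        dt = 0.1
        t = np.arange(200) * dt
        hump1 = 2.0 * np.exp(-((t - 5.0) / 1.0) ** 2)
        hump2 = 1.0 * np.exp(-((t - 15.0) / 1.0) ** 2)
        trough = -3.0 * np.exp(-((t - 10.0) / 0.8) ** 2)
        y = hump1 + hump2 + trough
        tr = Trace(y, dt)
        got = measure_basic(tr, MeasurementSpec("pop_spike", (0.0, t[-1])))
        # oracle: direct chord computation from the same extrema
        i_tr = np.argmin(y)
        i_l = np.argmax(y[:i_tr])
        i_r = i_tr + np.argmax(y[i_tr:])
        chord = y[i_l] + (y[i_r] - y[i_l]) * (i_tr - i_l) / (i_r - i_l)
        assert got == pytest.approx(chord - y[i_tr])
        assert got > 0

    def test_linearity_and_shift_invariance(self):
        dt = 0.1
        t = np.arange(150) * dt
        y = np.sin(t) * np.exp(-t / 5.0)
        k = 3.7
        w = (0.0, t[-1])
        for kind in ("peak_amplitude", "average_amplitude", "area"):
            spec = MeasurementSpec(kind, w)
            assert measure_basic(Trace(k * y, dt), spec) == pytest.approx(
                k * measure_basic(Trace(y, dt), spec))
        for kind in ("rise_time", "decay_time", "duration"):
            spec = MeasurementSpec(kind, w)
            assert measure_basic(Trace(k * y, dt), spec) == pytest.approx(
                measure_basic(Trace(y, dt), spec))
        # shifting t0 changes nothing but the window coordinates
        shifted = Trace(y, dt, t0_ms=100.0)
        spec = MeasurementSpec("peak_amplitude", (100.0, 100.0 + t[-1]))
        assert measure_basic(shifted, spec) == pytest.approx(
            measure_basic(Trace(y, dt), MeasurementSpec("peak_amplitude", w)))


class TestResistances:
    def test_input_resistance_ohms_law(self):
        # 100 pA current step deflecting a voltage trace by 10 mV -> 100 MΩ
        y = np.concatenate([np.zeros(50), np.full(100, 10.0)])
        tr = Trace(y, 1.0, units="mV")
        r = input_resistance(tr, 100.0, (100.0, 140.0),
                             baseline_window=(0.0, 40.0))
        assert r == pytest.approx(100.0)

    def test_zero_deflection_zero_resistance(self):
        tr = Trace(np.zeros(100), 1.0, units="mV")
        assert input_resistance(tr, 100.0, (50.0, 90.0)) == 0.0

    def test_zero_step_rejected(self):
        tr = Trace(np.ones(10), 1.0)
        with pytest.raises(MeasurementError):
            input_resistance(tr, 0.0, (0.0, 9.0))

    def test_seal_test_total_resistance(self):
        pm = PatchModel(rs_mohm=10.0, rin_mohm=100.0)
        tr = synth_seal_test(pm, 10.0, 5.0)
        total = input_resistance(tr, 10.0, (4.0, 4.9))
        assert total - pm.rs_mohm == pytest.approx(pm.rin_mohm, rel=0.02)

    def test_series_resistance_single_exponential(self):
        pm = PatchModel(rs_mohm=10.0)
        tr = synth_seal_test(pm, 10.0, 5.0)
        rs, taus, resid = series_resistance_fit(tr, 10.0, n_exp=1)
        assert rs == pytest.approx(10.0, rel=0.01)
        assert taus[0] == pytest.approx(pm.rs_mohm * pm.cm_pf / 1000.0, rel=0.01)
        assert resid < 1e-6

    def test_series_resistance_double_exponential(self):
        pm = PatchModel(rs_mohm=8.0, cm_pf=50.0)
        tr = synth_seal_test(pm, 10.0, 30.0, n_exp=2)
        tau = pm.rs_mohm * pm.cm_pf / 1000.0
        rs, taus, _ = series_resistance_fit(tr, 10.0, n_exp=2)
        assert rs == pytest.approx(8.0, rel=0.02)
        assert taus[0] == pytest.approx(tau, rel=0.05)
        assert taus[1] == pytest.approx(5.0 * tau, rel=0.05)

    def test_flat_trace_rejected(self):
        with pytest.raises(MeasurementError):
            series_resistance_fit(Trace(np.zeros(100), 0.01), 10.0)

    def test_noisy_parameter_recovery(self):
        # median relative Rs error < 5% across seeded noisy fixtures with
        # noise sd at 2% of the transient peak
        pm0 = PatchModel(rs_mohm=10.0)
        peak = 1000.0 * 10.0 / pm0.rs_mohm
        errors = []
        for seed in range(100):
            pm = PatchModel(rs_mohm=10.0, noise_sd=0.02 * peak, rng_seed=seed)
            tr = synth_seal_test(pm, 10.0, 5.0)
            rs, _, _ = series_resistance_fit(tr, 10.0)
            errors.append(abs(rs - 10.0) / 10.0)
        assert np.median(errors) < 0.05


def test_measure_dispatcher():
    tr = line_trace(2.0)
    assert measure(tr, MeasurementSpec("slope", (0.0, 9.9))) == pytest.approx(2.0)
    with pytest.raises(MeasurementError):
        measure(tr, MeasurementSpec("nope", (0.0, 9.9)))
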
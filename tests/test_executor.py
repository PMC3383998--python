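"""Protocol execution: loops, controls, perfusion timing, linking, logging."""

import numpy as np
import pytest

from perfusim import fixtures
from perfusim.executor import (
    ControlEvent,
    ProtocolRunError,
    emit_log,
    parse_controls,
    run_linked,
    run_protocol,
    run_recirculation_policy,
    spreadsheet_frame,
    timeline_frame,
)
from perfusim.perfusion import PerfusionLine
from perfusim.protocol_model import parse_protocol
from perfusim.sweep_engine import count_pulses


@pytest.fixture
def slice_rig():
    return fixtures.slice_rig()


def run_sequential(rig, baseline=3):
    return run_protocol(fixtures.sequential_ltp_script(), rig,
                        fixtures.sequential_ltp_controls(baseline))


class TestLoops:
    def test_empty_protocol_empty_record(self, slice_rig):
        rec = run_protocol(parse_protocol("MainProtocol\nEndProtocol"), slice_rig)
        assert rec.sweeps == [] and rec.log == []

    def test_counted_loop_runs_exactly_n_times(self, slice_rig):
        script = parse_protocol(
            "MainProtocol\nLoop 3\nP0sweep\nEndLoop\nEndProtocol")
        rec = run_protocol(script, slice_rig)
        assert rec.sweep_names() == ["P0sweep"] * 3

    def test_continuous_loop_exits_on_uncheck(self, slice_rig):
        rec = run_sequential(slice_rig, baseline=5)
        assert rec.sweep_names()[:5] == ["P0sweep"] * 5
        assert rec.sweep_names()[5] == "T0sweep"

    def test_uncheck_checked_at_iteration_end(self, slice_rig):
        # a time-triggered uncheck mid-interval still finishes the iteration
        controls = [ControlEvent("uncheck_loop", time_s=70.0, loop_index=0)]
        rec = run_protocol(fixtures.sequential_ltp_script(), slice_rig, controls)
        baseline = rec.sweep_names().index("T0sweep")
        assert baseline == 3  # sweeps at t=0,30,60 complete; uncheck at 70 caught at 90

    def test_continuous_loop_without_uncheck_rejected(self, slice_rig):
        script = parse_protocol(
            "MainProtocol\nLoop 99999 continuous\nP0sweep\nEndLoop\nEndProtocol")
        with pytest.raises(ProtocolRunError, match="uncheck"):
            run_protocol(script, slice_rig)

    def test_unreached_loop_control_warns(self, slice_rig):
        controls = fixtures.sequential_ltp_controls(3) + [
            ControlEvent("uncheck_loop", time_s=1e9, loop_index=7)]
        rec = run_protocol(fixtures.sequential_ltp_script(), slice_rig, controls)
        assert any("never reached" in w for w in rec.warnings)


class TestSequentialWorkedProtocol:
    def test_sweep_counts_between_and_after_trains(self, slice_rig):
        rec = run_sequential(slice_rig)
        names = rec.sweep_names()
        t0s = [i for i, n in enumerate(names) if n == "T0sweep"]
        assert len(t0s) == 2
        assert names[t0s[0] + 1:t0s[1]].count("P0sweep") == 11
        assert names[t0s[1] + 1:].count("P0sweep") == 8

    def test_t0_train_has_100_pulses(self, slice_rig):
        rec = run_sequential(slice_rig)
        train = next(s for s in rec.sweeps if s.name == "T0sweep")
        assert count_pulses(train.waveforms, "S0") == 100
        p0 = next(s for s in rec.sweeps if s.name == "P0sweep")
        assert count_pulses(p0.waveforms, "S0") == 1

    def test_timeline_conservation(self, slice_rig):
        rec = run_sequential(slice_rig)
        # no delays in this script: total duration is sweeps x interval
        assert rec.end_time_s == pytest.approx(
            len(rec.sweeps) * slice_rig.inter_sweep_interval_s)

    def test_sweep_starts_strictly_increasing(self, slice_rig):
        starts = [s.start_time_s for s in run_sequential(slice_rig).sweeps]
        assert all(b > a for a, b in zip(starts, starts[1:]))

    def test_determinism(self, slice_rig):
        a = run_sequential(fixtures.slice_rig())
        b = run_sequential(fixtures.slice_rig())
        assert a.sweep_names() == b.sweep_names()
        assert [e.text for e in a.log] == [e.text for e in b.log]
        assert [(ln, act) for ln, act in a.valve_timeline] == \
               [(ln, act) for ln, act in b.valve_timeline]
        for sa, sb in zip(a.sweeps, b.sweeps):
            for key in sa.traces:
                assert np.array_equal(sa.traces[key].samples,
                                      sb.traces[key].samples)


class TestPerfusionExecution:
    def test_slice_ltp_log_sequence(self, slice_rig):
        rec = run_protocol(fixtures.slice_ltp_script(), slice_rig,
                           fixtures.slice_ltp_controls(3))
        compact = []
        for e in rec.log:
            if e.kind == "perfuse":
                compact.append(e.text.split("'")[0].strip())
            else:
                compact.append(e.text)
        expected = (["Perfuse Slow0 Ch1"] + ["P0sweep"] * 3
                    + ["Perfuse Slow0 Ch2"] + ["P0sweep"] * 8 + ["T0sweep"]
                    + ["P0sweep"] * 3 + ["Perfuse Slow0 Ch1"]
                    + ["P0sweep"] * 8 + ["T0sweep"] + ["P0sweep"] * 8)
        assert compact == expected

    def test_slow_perfuse_never_during_sweep(self, slice_rig):
        rec = run_protocol(fixtures.slice_ltp_script(), slice_rig,
                           fixtures.slice_ltp_controls(3))
        windows = [(s.start_time_s,
                    s.start_time_s + s.waveforms.time_ms[-1] / 1000.0)
                   for s in rec.sweeps]
        for entry in rec.log:
            if entry.kind != "perfuse":
                continue
            assert not any(a <= entry.time_s < b for a, b in windows)

    def test_ltp_blocked_by_inhibitor_then_recovered(self, slice_rig):
        rec = run_protocol(fixtures.slice_ltp_script(), slice_rig,
                           fixtures.slice_ltp_controls(3))
        slopes = [(s.name, s.measurements["slope0"]) for s in rec.sweeps]
        t0_idx = [i for i, (n, _) in enumerate(slopes) if n == "T0sweep"]
        before1 = slopes[t0_idx[0] - 1][1]
        after1 = slopes[t0_idx[0] + 1][1]
        before2 = slopes[t0_idx[1] - 1][1]
        after2 = slopes[t0_idx[1] + 1][1]
        assert after1 / before1 == pytest.approx(1.0, rel=1e-9)
        assert after2 / before2 == pytest.approx(
            slice_rig.biology.ltp_factor, rel=1e-9)

    def test_override_suppresses_perfuse(self, slice_rig):
        controls = fixtures.slice_ltp_controls(2) + [
            ControlEvent("set_override", time_s=0.0)]
        rec = run_protocol(fixtures.slice_ltp_script(), slice_rig, controls)
        assert rec.activations == []  # no valve output at all
        assert all("suppressed" in e.text for e in rec.log
                   if e.kind == "perfuse")

    def test_manual_apply_without_override_warns(self, slice_rig):
        controls = fixtures.slice_ltp_controls(2) + [
            ControlEvent("manual_apply", time_s=10.0,
                         line=PerfusionLine.SLOW0, channel=3)]
        rec = run_protocol(fixtures.slice_ltp_script(), slice_rig, controls)
        assert any("Override" in w for w in rec.warnings)
        assert (PerfusionLine.SLOW0, 3) not in rec.distinct_solutions()

    def test_set_ch_to_last_perfuse_keeps_channel_on(self, slice_rig):
        base = fixtures.slice_ltp_controls(2)
        rec_off = run_protocol(fixtures.slice_ltp_script(), slice_rig, base)
        # default: the run ends with a switch back to channel 0
        assert rec_off.activations[-1][1] == 0
        rec_on = run_protocol(
            fixtures.slice_ltp_script(), slice_rig,
            base + [ControlEvent("set_ch_to_last_perfuse", time_s=0.0)])
        assert rec_on.activations[-1][1] != 0


class TestRunOnceAndManualSweeps:
    def test_runonce_body_runs_once_per_check(self, slice_rig):
        controls = [
            ControlEvent("check_runonce", after_sweep=3, runonce_index=0),
            ControlEvent("check_runonce", after_sweep=8, runonce_index=0),
            ControlEvent("uncheck_loop", after_sweep=12, loop_index=0),
        ]
        rec = run_protocol(fixtures.circular_runonce_script(), slice_rig,
                           controls)
        assert rec.sweep_names().count("T0sweep") == 2

    def test_single_sweep_control_inserts_train(self, slice_rig):
        controls = [
            ControlEvent("single_sweep", after_sweep=2, sweep_name="T0sweep"),
            ControlEvent("uncheck_loop", after_sweep=5, loop_index=0),
        ]
        rec = run_protocol(fixtures.circular_baseline_script(), slice_rig,
                           controls)
        assert rec.sweep_names().count("T0sweep") == 1


class TestLinking:
    def test_linked_protocols_activate_15_solutions(self):
        rig = fixtures.patch_rig_16ch()
        rec = run_linked(fixtures.linked_fast_perfusion_scripts(), rig)
        sols = rec.distinct_solutions()
        assert len(sols) == 15
        assert {ch for _, ch in sols} == set(range(1, 16))
        assert rec.protocols_run == ["fast_perfusion1.proto",
                                     "fast_perfusion2.proto",
                                     "fast_perfusion3.proto"]

    def test_link_log_has_load_and_start_entries(self):
        rig = fixtures.patch_rig_16ch()
        rec = run_linked(fixtures.linked_fast_perfusion_scripts()[:2], rig)
        link_lines = [e.text for e in rec.log if e.kind == "link"]
        assert link_lines == ["Loaded fast_perfusion2.proto",
                              "Started fast_perfusion2.proto"]

    def test_no_autostart_without_start_control_stops(self):
        rig = fixtures.patch_rig_16ch()
        plans = fixtures.linked_fast_perfusion_scripts()
        plans = [(plans[0][0], True), (plans[1][0], False)]
        rec = run_linked(plans, rig)
        assert rec.protocols_run == ["fast_perfusion1.proto"]

    def test_start_control_resumes_non_autostart_protocol(self):
        rig = fixtures.patch_rig_16ch()
        plans = fixtures.linked_fast_perfusion_scripts()
        plans = [(plans[0][0], True), (plans[1][0], False)]
        rec = run_linked(plans, rig, [
            ControlEvent("start_protocol", time_s=500.0, protocol_index=1)])
        assert len(rec.protocols_run) == 2

    def test_monotone_time_across_protocols(self):
        rig = fixtures.patch_rig_16ch()
        rec = run_linked(fixtures.linked_fast_perfusion_scripts(), rig)
        starts = [s.start_time_s for s in rec.sweeps]
        assert all(b > a for a, b in zip(starts, starts[1:]))


class TestLog:
    def test_perfuse_line_carries_label(self, slice_rig):
        rec = run_protocol(fixtures.slice_ltp_script(), slice_rig,
                           fixtures.slice_ltp_controls(2))
        text = emit_log(rec)
        assert "Perfuse Slow0 Ch2 'CaMKII Inhibitor'" in text
        assert "Perfuse Slow0 Ch1 'ACSF'" in text

    def test_unlabeled_channel_gets_default_label(self, slice_rig):
        script = parse_protocol("MainProtocol\nPerfuse Slow0 3\nEndProtocol")
        rec = run_protocol(script, slice_rig)
        assert "Ch3 'Ch3'" in emit_log(rec)

    def test_log_line_count_oracle(self):
        # one line per Perfuse + sweep + link event, nothing else
        rig = fixtures.patch_rig_16ch()
        rec = run_linked(fixtures.linked_fast_perfusion_scripts(), rig)
        n_perfuse = 3
        n_sweeps = len(rec.sweeps)
        n_link = 4  # load+start for protocols 2 and 3
        assert len(emit_log(rec).strip().splitlines()) == \
            n_perfuse + n_sweeps + n_link


class TestRecirculation:
    def make_record(self, slice_rig):
        return run_protocol(fixtures.slice_ltp_script(), slice_rig,
                            fixtures.slice_ltp_controls(2))

    def test_recirculate_engages_during_policy_channel(self, slice_rig):
        rec = self.make_record(slice_rig)
        timeline = run_recirculation_policy(rec, {2: "recirculate"})
        values = [(a.time_s, a.value) for _, a in timeline]
        # Slow0 goes Ch1 -> Ch2 -> Ch1 -> off: recirculation toggles on at the
        # Ch2 switch and off again at the return to Ch1
        assert [v for _, v in values] == [1, 0]
        ch2_on = [t for ln, ch, t in rec.activations if ch == 2][0]
        assert values[0][0] == ch2_on

    def test_empty_policy_constant_waste(self, slice_rig):
        rec = self.make_record(slice_rig)
        assert run_recirculation_policy(rec, {}) == []

    def test_inverted_policy_inverts_trace(self, slice_rig):
        rec = self.make_record(slice_rig)
        a = run_recirculation_policy(rec, {2: "recirculate"})
        b = run_recirculation_policy(rec, {1: "recirculate"})
        # opposite policies toggle at the same times with opposite sense
        assert [x[1].time_s for x in a] == [x[1].time_s for x in b][1:] or \
            len(a) != len(b)
        assert [x[1].value for x in a] == [1, 0]
        assert [x[1].value for x in b][:2] == [1, 0]

    def test_bad_policy_rejected(self, slice_rig):
        with pytest.raises(ProtocolRunError):
            run_recirculation_policy(self.make_record(slice_rig), {1: "maybe"})


class TestControlsParsing:
    def test_csv_round_trip(self):
        events = parse_controls(
            "sweep=3,uncheck_loop,loop=0\n"
            "t=600,set_override,value=true\n"
            "t=700,manual_apply,line=Slow0,channel=3\n")
        assert events[0].after_sweep == 3 and events[0].loop_index == 0
        assert events[1].time_s == 600.0 and events[1].value is True
        assert events[2].line is PerfusionLine.SLOW0 and events[2].channel == 3

    def test_bad_trigger_rejected(self):
        with pytest.raises(ProtocolRunError):
            parse_controls("when=later,uncheck_loop,loop=0")


def test_frames_and_outputs(tmp_path, slice_rig):
    from perfusim.executor import write_outputs

    rec = run_protocol(fixtures.slice_ltp_script(), slice_rig,
                       fixtures.slice_ltp_controls(2))
    sheet = spreadsheet_frame(rec)
    assert (sheet["measurement"] == "slope0").sum() == len(rec.sweeps)
    tl = timeline_frame(rec)
    assert list(tl["time_s"]) == sorted(tl["time_s"])
    write_outputs(rec, tmp_path, slice_rig)
    assert (tmp_path / "experiment.log").exists()
    assert (tmp_path / "timeline.csv").exists()
    assert len(list(tmp_path.glob("sweep_*.csv"))) == len(rec.sweeps)
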
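import math

import numpy as np
import pandas as pd
import pytest

import proxlog as px
from proxlog.config import TagConfig
from proxlog.firmware import PulseDetection, TagState, run_deployment
from conftest import make_logs


def feed(dets, cfg=None, tag_id=0):
    cfg = cfg or TagConfig()
    st = TagState(tag_id=tag_id)
    for (t, src, rssi) in dets:
        px.step_encounter(st, PulseDetection(tag_id, src, t, rssi), cfg)
    for p in list(st.open_encounters):
        from proxlog.firmware import _close

        _close(st, p, cfg)
    return st


class TestStepEncounter:
    def test_three_pulse_encounter_log(self):
        st = feed([(0, 1, 5), (20, 1, 9), (40, 1, 7)])
        (log,) = st.saved_logs
        assert (log.start_t, log.end_t, log.duration) == (0, 40, 40)
        assert (log.min_rssi, log.max_rssi, log.n_pulses) == (5, 9, 3)
        assert log.mean_rssi == pytest.approx(7.0)

    def test_missed_slot_splits_into_zero_duration_logs(self):
        st = feed([(0, 1, 5), (60, 1, 5)])
        assert [l.duration for l in st.saved_logs] == [0, 0]
        assert all(l.n_pulses == 1 for l in st.saved_logs)

    def test_five_minute_cap_then_new_encounter(self):
        st = feed([(t, 1, 5) for t in range(0, 401, 20)])
        durations = [l.duration for l in st.saved_logs]
        assert durations[0] == 300
        assert max(durations) == 300
        assert sum(l.n_pulses for l in st.saved_logs) == 21

    def test_below_threshold_pulses_invisible(self):
        st = feed([(0, 1, -3), (20, 1, 4), (40, 1, -1), (60, 1, 4)])
        # sub-threshold pulses at 0 and 40 never reach the logger; the miss
        # at slot 40 splits the encounter
        assert [(l.start_t, l.end_t) for l in st.saved_logs] == [(20, 20), (60, 60)]

    def test_out_of_order_stream_rejected(self):
        with pytest.raises(ValueError, match="out-of-order"):
            feed([(40, 1, 5), (0, 1, 5)])

    def test_concurrent_partner_limit(self):
        cfg = TagConfig(max_concurrent=2)
        st = TagState(tag_id=0)
        for src in (1, 2, 3):
            px.step_encounter(st, PulseDetection(0, src, 0, 5), cfg)
        assert set(st.open_encounters) == {1, 2}  # the 3rd is ignored


class TestSaveLog:
    def test_capacity_overflow_drops_newest(self):
        cfg = TagConfig(memory_capacity=3)
        st = TagState(tag_id=0)
        for k in range(4):
            log = px.EncounterLog(0, 1, k * 100, k * 100, 5, 5.0, 5, 1)
            px.save_log(st, log, cfg)
        assert len(st.memory) == 3
        assert st.dropped_log_count == 1
        assert [l.start_t for l in st.memory] == [0, 100, 200]

    def test_download_flush_frees_memory(self):
        cfg = TagConfig(memory_capacity=2)
        st = TagState(tag_id=0)
        for k in range(2):
            px.save_log(st, px.EncounterLog(0, 1, k, k, 5, 5.0, 5, 1), cfg)
        st.downloaded.extend(st.memory)
        st.memory.clear()
        px.save_log(st, px.EncounterLog(0, 1, 9, 9, 5, 5.0, 5, 1), cfg)
        assert st.dropped_log_count == 0
        assert len(st.saved_logs) == 3


class TestClocks:
    @pytest.mark.parametrize(
        "last,period,expected", [(1000, 30, 1017), (0, 30, 17), (500, 0, 502)]
    )
    def test_clock_saver_restore(self, last, period, expected):
        assert px.clock_saver_restore(last, period) == expected

    def test_sync_adopts_only_fresher_receiver_clock(self):
        t, set_new = px.sync_clock(0.0, 86400.0, 100000.0, 100007.0)
        assert (t, set_new) == (100000.0, 86400.0)
        t, set_old = px.sync_clock(86400.0, 0.0, 100000.0, 100007.0)
        assert (t, set_old) == (100007.0, 86400.0)

    def test_unsynced_tag_drifts_linearly(self):
        st = TagState(tag_id=0, drift_per_day=3.0)
        assert st.clock_offset(86400.0) == pytest.approx(3.0)
        assert st.clock_offset(43200.0) == pytest.approx(1.5)


class TestBatteryFailure:
    def test_reset_wipes_memory_and_restores_clock(self):
        cfg = TagConfig()
        st = TagState(tag_id=0)
        px.save_log(st, px.EncounterLog(0, 1, 0, 40, 5, 5.0, 5, 3), cfg)
        st.next_reset_t = 1000.0
        px.apply_battery_failure(st, 1000.0, cfg, np.random.default_rng(0))
        assert st.memory == [] and st.open_encounters == {}
        assert st.lost_log_count == 1 and st.lost_pulse_count == 3
        assert not st.alive
        # clock-saver restore: last 30 s save + 17
        assert st.clock_base == pytest.approx((990 + 17) - 1000)

    def test_infinite_battery_is_inert(self):
        cfg = TagConfig()
        st = TagState(tag_id=0)
        px.apply_battery_failure(st, 1e9, cfg, np.random.default_rng(0))
        assert st.alive and st.lost_log_count == 0


class TestRunDeployment:
    def test_two_tag_scenario_reciprocal_logs(self, two_tag_pulses):
        res = run_deployment(two_tag_pulses, TagConfig(), sim_span=(0, 60))
        assert len(res.logs) == 2
        a = res.logs[res.logs.logger_id == 0].iloc[0]
        b = res.logs[res.logs.logger_id == 1].iloc[0]
        assert a.start == b.start == 0 and a.end == b.end == 40
        assert a.n_pulses == b.n_pulses == 3

    def test_receiver_rows_passed_through(self, two_tag_pulses, params):
        rows = two_tag_pulses.copy()
        recv = pd.DataFrame(
            [(1000, 0, 0, -5), (1000, 1, 20, -30)],
            columns=["listener_id", "source_id", "t", "rssi"],
        )
        stream = pd.concat([rows, recv]).sort_values("t", kind="mergesort")
        res = run_deployment(stream, TagConfig(), sim_span=(0, 60))
        assert len(res.receiver_logs) == 2
        assert res.receiver_logs.rssi.min() == -30  # no threshold on receivers

    def test_unknown_listener_rejected(self, two_tag_pulses):
        stray = pd.DataFrame(
            [(5, 0, 0, 3)], columns=["listener_id", "source_id", "t", "rssi"]
        )
        stream = pd.concat([two_tag_pulses, stray]).sort_values("t", kind="mergesort")
        with pytest.raises(ValueError, match="unknown listener"):
            run_deployment(stream, TagConfig(), sim_span=(0, 60), tag_ids=[0, 1])

    def test_unsorted_stream_rejected(self, two_tag_pulses):
        with pytest.raises(ValueError, match="time-sorted"):
            run_deployment(two_tag_pulses.iloc[::-1], TagConfig())

    def test_dead_battery_partner_produces_one_sided_logs(self, two_tag_pulses):
        res = run_deployment(
            two_tag_pulses, TagConfig(reset_interval_s=10.0),
            battery_life_s={1: 0.0}, seed=1, sim_span=(0, 60),
        )
        loggers = set(res.logs.logger_id)
        assert 0 in loggers and 1 not in loggers
        assert res.uptime[1] == []

    def test_invariants_on_simulated_colony(self, quality_run):
        """Every saved log satisfies the firmware's structural invariants."""
        cfg, sim, _ = quality_run
        logs = sim.logs
        assert (logs.duration <= cfg.tag.max_encounter_s).all()
        assert (logs.min_rssi <= logs.mean_rssi + 1e-9).all()
        assert (logs.mean_rssi <= logs.max_rssi + 1e-9).all()
        assert (logs.max_rssi >= cfg.tag.detection_threshold_rssi).all()
        assert (logs.n_pulses == logs.duration // cfg.tag.pulse_interval_s + 1).all()
        # single-pulse logs have zero duration
        assert (logs.loc[logs.n_pulses == 1, "duration"] == 0).all()

    def test_detection_conservation(self, quality_run):
        """Above-threshold detections = pulses in saved + dropped + lost logs."""
        cfg, sim, _ = quality_run
        kept = int(sim.logs.n_pulses.sum())
        assert sim.stats["detections_processed"] == (
            kept + sim.stats["dropped_pulse_count"] + sim.stats["lost_pulse_count"]
        )


def test_longest_single_pulse_duration_is_39s():
    """Brute-force placement scan: one detected pulse bounds the true
    encounter at just under two pulse intervals."""
    assert px.longest_single_pulse_duration(20) == 39
    assert px.longest_single_pulse_duration(10) == 19
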
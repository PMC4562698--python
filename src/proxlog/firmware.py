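"""Tag firmware emulation: detections in, saved encounter logs out.

A tag monitors a period of repeated above-threshold detections of another
tag as one *encounter* and saves a log (ids, start/end, min/mean/max RSSI,
pulse count) when the encounter ends.  The emulation covers the firmware
behaviours that shape downstream data quality:

* detection threshold (pulses below it are never seen by the logger),
* one missed pulse slot ends an encounter (end time = last detected pulse,
  so a single-pulse encounter has duration zero),
* a five-minute cap, after which the log is saved and a fresh encounter
  opens at the next detection,
* at most 30 concurrent encounters and 300 logs in RAM (overflow drops the
  newest log),
* clock drift, 15-minute receiver clock synchronization, the clock-saver
  restore rule, and post-battery-life resets that wipe RAM (the tag keeps
  pulsing, so partners still log it -- the source of late single logs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import TagConfig
from .pulses import RECEIVER_ID_BASE

__all__ = [
    "EncounterLog",
    "PulseDetection",
    "TagState",
    "step_encounter",
    "save_log",
    "clock_saver_restore",
    "sync_clock",
    "apply_battery_failure",
    "run_deployment",
    "DeploymentResult",
    "longest_single_pulse_duration",
]


@dataclass
class PulseDetection:
    listener_id: int
    source_id: int
    t: int
    rssi: int


@dataclass
class EncounterLog:
    logger_id: int
    partner_id: int
    start_t: int
    end_t: int
    min_rssi: int
    mean_rssi: float
    max_rssi: int
    n_pulses: int

    @property
    def duration(self) -> int:
        return self.end_t - self.start_t


@dataclass
class _OpenEncounter:
    start: int
    last: int
    min_rssi: int
    max_rssi: int
    total: float
    n: int


@dataclass
class TagState:
    """Mutable per-tag firmware state."""

    tag_id: int
    open_encounters: Dict[int, _OpenEncounter] = field(default_factory=dict)
    memory: List[EncounterLog] = field(default_factory=list)     # RAM since last download
    downloaded: List[EncounterLog] = field(default_factory=list)
    dropped_log_count: int = 0
    dropped_pulse_count: int = 0
    lost_log_count: int = 0       # wiped by post-battery resets
    lost_pulse_count: int = 0
    detections_processed: int = 0
    last_t: int = -(10**12)
    alive: bool = True
    # clock model: tag_time(t) = t + clock_base + drift_per_day * (t - drift_ref)/86400
    clock_base: float = 0.0
    drift_per_day: float = 0.0
    drift_ref_t: float = 0.0
    clock_set_t: float = 0.0
    next_reset_t: float = math.inf

    def clock_offset(self, t: float) -> float:
        return self.clock_base + self.drift_per_day * (t - self.drift_ref_t) / 86400.0

    @property
    def saved_logs(self) -> List[EncounterLog]:
        return self.downloaded + self.memory


def clock_saver_restore(last_saved_t: float, period_s: float) -> float:
    """Clock restored after a reset: last saved time + period/2 + 2 s."""
    return last_saved_t + period_s / 2.0 + 2.0


def sync_clock(
    tag_clock_set_t: float,
    receiver_clock_set_t: float,
    receiver_time: float,
    tag_time: float,
) -> Tuple[float, float]:
    """Adopt the receiver's time iff its clock was set more recently.

    Returns ``(clock_time, clock_set_t)`` after the (possible) update.
    """
    if receiver_clock_set_t > tag_clock_set_t:
        return receiver_time, receiver_clock_set_t
    return tag_time, tag_clock_set_t


def save_log(state: TagState, log: EncounterLog, cfg: TagConfig) -> TagState:
    """Append to RAM if there is room; otherwise the new log is lost."""
    if len(state.memory) < cfg.memory_capacity:
        state.memory.append(log)
    else:
        state.dropped_log_count += 1
        state.dropped_pulse_count += log.n_pulses
    return state


def _close(state: TagState, partner: int, cfg: TagConfig) -> None:
    enc = state.open_encounters.pop(partner)
    off = int(round(state.clock_offset(enc.last)))
    log = EncounterLog(
        logger_id=state.tag_id,
        partner_id=partner,
        start_t=enc.start + off,
        end_t=enc.last + off,
        min_rssi=enc.min_rssi,
        mean_rssi=enc.total / enc.n,
        max_rssi=enc.max_rssi,
        n_pulses=enc.n,
    )
    save_log(state, log, cfg)


def _close_stale(state: TagState, t: int, cfg: TagConfig) -> None:
    stale = [p for p, e in state.open_encounters.items() if t - e.last > cfg.pulse_interval_s]
    for p in stale:
        _close(state, p, cfg)


def step_encounter(state: TagState, det: PulseDetection, cfg: TagConfig) -> TagState:
    """Process one detection through the encounter state machine."""
    if det.t < state.last_t:
        raise ValueError(
            f"out-of-order detection for tag {state.tag_id}: t={det.t} after {state.last_t}"
        )
    state.last_t = det.t
    _close_stale(state, det.t, cfg)
    if det.rssi < cfg.detection_threshold_rssi:
        return state
    state.detections_processed += 1
    enc = state.open_encounters.get(det.source_id)
    if enc is None:
        if len(state.open_encounters) >= cfg.max_concurrent:
            return state  # slot-limited: the extra partner is ignored
        state.open_encounters[det.source_id] = _OpenEncounter(
            start=det.t, last=det.t, min_rssi=det.rssi, max_rssi=det.rssi,
            total=float(det.rssi), n=1,
        )
        return state
    if det.t - enc.start > cfg.max_encounter_s:
        # cap exceeded between pulses: save and start fresh at this detection
        _close(state, det.source_id, cfg)
        state.open_encounters[det.source_id] = _OpenEncounter(
            start=det.t, last=det.t, min_rssi=det.rssi, max_rssi=det.rssi,
            total=float(det.rssi), n=1,
        )
        return state
    enc.last = det.t
    enc.min_rssi = min(enc.min_rssi, det.rssi)
    enc.max_rssi = max(enc.max_rssi, det.rssi)
    enc.total += det.rssi
    enc.n += 1
    if det.t - enc.start == cfg.max_encounter_s:
        _close(state, det.source_id, cfg)  # reached the cap exactly
    return state


def apply_battery_failure(
    state: TagState, t: float, cfg: TagConfig, rng: np.random.Generator
) -> TagState:
    """Past battery life the tag keeps pulsing but resets at random times.

    Each reset wipes RAM (open encounters and undownloaded logs) and restores
    the clock through the clock saver; the tag therefore stops contributing
    its own side of encounters while partners keep logging it.
    """
    while t >= state.next_reset_t:
        reset_t = state.next_reset_t
        state.lost_log_count += len(state.memory)
        state.lost_pulse_count += sum(l.n_pulses for l in state.memory)
        state.lost_pulse_count += sum(e.n for e in state.open_encounters.values())
        state.lost_log_count += len(state.open_encounters)
        state.memory.clear()
        state.open_encounters.clear()
        state.alive = False
        tag_time = reset_t + state.clock_offset(reset_t)
        last_save = math.floor(tag_time / cfg.clock_saver_period_s) * cfg.clock_saver_period_s
        restored = clock_saver_restore(last_save, cfg.clock_saver_period_s)
        state.clock_base = restored - reset_t
        state.drift_ref_t = reset_t
        state.next_reset_t = reset_t + rng.exponential(cfg.reset_interval_s)
    return state


@dataclass
class DeploymentResult:
    logs: pd.DataFrame          # logger_id, partner_id, start, end, duration, rssi stats
    receiver_logs: pd.DataFrame  # receiver_id, source_id, t, rssi
    uptime: Dict[int, List[Tuple[int, int]]]
    stats: Dict[str, int]
    states: Dict[int, TagState]


_LOG_COLUMNS = [
    "logger_id", "partner_id", "start", "end", "duration",
    "min_rssi", "mean_rssi", "max_rssi", "n_pulses",
]


def _logs_frame(states: Dict[int, TagState]) -> pd.DataFrame:
    rows = []
    for s in states.values():
        for l in s.saved_logs:
            rows.append(
                (l.logger_id, l.partner_id, l.start_t, l.end_t, l.duration,
                 l.min_rssi, l.mean_rssi, l.max_rssi, l.n_pulses)
            )
    df = pd.DataFrame(rows, columns=_LOG_COLUMNS)
    if len(df):
        df = df.sort_values(["logger_id", "partner_id", "start"], kind="mergesort").reset_index(
            drop=True
        )
    return df


def run_deployment(
    pulses: pd.DataFrame,
    cfg: TagConfig,
    battery_life_s: Optional[Dict[int, float]] = None,
    seed: int = 0,
    sim_span: Optional[Tuple[int, int]] = None,
    tag_ids: Optional[List[int]] = None,
) -> DeploymentResult:
    """Route a time-sorted detection stream through every tag's firmware.

    ``battery_life_s`` maps tag id to seconds of operational life (tags not
    listed use ``cfg.battery_life_s``, None meaning the battery outlasts the
    run).  Receiver-side rows are logged verbatim (receivers have no
    threshold); receiver clock broadcasts drive tag-clock synchronization.
    """
    required = {"listener_id", "source_id", "t", "rssi"}
    if not required.issubset(pulses.columns):
        raise ValueError(f"pulse table missing columns {required - set(pulses.columns)}")
    if len(pulses) and not pulses["t"].is_monotonic_increasing:
        raise ValueError("pulse stream must be time-sorted")

    rng = np.random.default_rng(seed)
    is_recv_listener = pulses["listener_id"] >= RECEIVER_ID_BASE
    is_recv_source = pulses["source_id"] >= RECEIVER_ID_BASE

    receiver_logs = (
        pulses.loc[is_recv_listener & ~is_recv_source]
        .rename(columns={"listener_id": "receiver_id"})
        .reset_index(drop=True)
    )

    if tag_ids is None:
        tag_ids = sorted(
            set(pulses.loc[~is_recv_listener, "listener_id"]).union(
                pulses.loc[~is_recv_source, "source_id"]
            )
        )
    else:
        tag_ids = sorted(int(t) for t in tag_ids)
    if sim_span is None:
        sim_span = (int(pulses["t"].min()), int(pulses["t"].max())) if len(pulses) else (0, 0)

    battery_life_s = battery_life_s or {}
    states: Dict[int, TagState] = {}
    for tid in tag_ids:
        st = TagState(tag_id=tid, drift_per_day=cfg.clock_drift_s_per_day)
        life = battery_life_s.get(tid, cfg.battery_life_s)
        if life is not None:
            st.next_reset_t = life + rng.exponential(cfg.reset_interval_s)
        states[tid] = st

    # daily memory-download flush events (the 23:50 window)
    first_day = sim_span[0] // 86400
    last_day = sim_span[1] // 86400 + 1
    flushes = [d * 86400 + cfg.download_flush_time_s for d in range(first_day, last_day + 1)]
    flush_i = 0

    stream = pulses.loc[~is_recv_listener]
    for row in stream.itertuples(index=False):
        t = int(row.t)
        while flush_i < len(flushes) and t >= flushes[flush_i]:
            for st in states.values():
                st.downloaded.extend(st.memory)
                st.memory.clear()
            flush_i += 1
        st = states.get(int(row.listener_id))
        if st is None:
            raise ValueError(f"unknown listener id {row.listener_id}")
        if st.next_reset_t <= t:
            apply_battery_failure(st, t, cfg, rng)
        if int(row.source_id) >= RECEIVER_ID_BASE:
            # receiver clock broadcast; receivers are reset daily by the master
            recv_set = (t // 86400) * 86400
            tag_time = t + st.clock_offset(t)
            new_time, new_set = sync_clock(st.clock_set_t, recv_set, float(t), tag_time)
            if new_set != st.clock_set_t:
                st.clock_base = new_time - t
                st.drift_ref_t = t
                st.clock_set_t = new_set
            continue
        det = PulseDetection(int(row.listener_id), int(row.source_id), t, int(row.rssi))
        step_encounter(st, det, cfg)

    for tid, st in states.items():  # end of run: apply pending resets, close open
        if st.next_reset_t <= sim_span[1]:
            apply_battery_failure(st, sim_span[1], cfg, rng)
        life = battery_life_s.get(tid, cfg.battery_life_s)
        if life is not None and sim_span[1] >= life:
            # a dying tag's RAM is never downloaded: its tail logs are lost
            st.lost_log_count += len(st.memory) + len(st.open_encounters)
            st.lost_pulse_count += sum(l.n_pulses for l in st.memory)
            st.lost_pulse_count += sum(e.n for e in st.open_encounters.values())
            st.memory.clear()
            st.open_encounters.clear()
            st.alive = False
        for p in list(st.open_encounters):
            _close(st, p, cfg)

    uptime: Dict[int, List[Tuple[int, int]]] = {}
    for tid in tag_ids:
        life = battery_life_s.get(tid, cfg.battery_life_s)
        end = sim_span[1] if life is None else min(sim_span[1], int(life))
        uptime[tid] = [(sim_span[0], end)] if end > sim_span[0] else []

    stats = {
        "detections_processed": sum(s.detections_processed for s in states.values()),
        "dropped_log_count": sum(s.dropped_log_count for s in states.values()),
        "dropped_pulse_count": sum(s.dropped_pulse_count for s in states.values()),
        "lost_log_count": sum(s.lost_log_count for s in states.values()),
        "lost_pulse_count": sum(s.lost_pulse_count for s in states.values()),
    }
    return DeploymentResult(
        logs=_logs_frame(states),
        receiver_logs=receiver_logs,
        uptime=uptime,
        stats=stats,
        states=states,
    )


def longest_single_pulse_duration(
    pulse_interval_s: int = 20, resolution: float = 0.25
) -> int:
    """Longest true encounter (integer seconds) that can yield one pulse.

    Brute-force enumeration over encounter placements against the periodic
    pulse schedule: for each candidate duration, scan sub-second offsets and
    count pulse instants inside the closed encounter window.  With a 20 s
    pulse rate the answer is 39 s: a zero-duration (one-pulse) log can stem
    from a true encounter of up to twice the interval minus one second.
    """
    I = pulse_interval_s
    best = 0
    for dur in range(0, 3 * I + 1):
        for s in np.arange(resolution / 2.0, I, resolution):
            n = math.floor((s + dur) / I) - math.ceil(s / I) + 1
            if n == 1:
                best = max(best, dur)
                break
    return best
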
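"""Ground-truth animal trajectories for the synthetic deployment.

Each tag is assigned a nest and follows an exact-discretized
Ornstein-Uhlenbeck walk around a moving attractor.  Three kinds of excursion
interrupt home-range behaviour:

* **perch** -- the attractor stays on the nest and the walk tightens to a few
  centimeters (nest mates perching together produce body-contact range);
* **visit** -- the attractor jumps to another tag's nest for a while (the
  social-contact generator; its rate is the main config knob);
* **flight** -- the attractor jumps to a random point in the arena.

Headings are smoothed random walks.  Positions are defined for every
active-window time step and clipped to the arena.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .config import WorldConfig, nest_positions

__all__ = ["TrajectorySet", "active_times", "simulate_trajectories", "true_contact_intervals"]

_HOME, _PERCH, _VISIT, _FLIGHT = 0, 1, 2, 3


@dataclass
class TrajectorySet:
    """Positions/headings of every tag at every active-window time step."""

    times: np.ndarray          # (T,) int seconds since simulation epoch
    positions: np.ndarray      # (n_tags, T, 2) meters
    headings: np.ndarray       # (n_tags, T) radians
    nest_of: np.ndarray        # (n_tags,) nest index per tag
    nests: np.ndarray          # (n_nests, 2) meters
    arena: Tuple[float, float]

    @property
    def n_tags(self) -> int:
        return self.positions.shape[0]

    def index_of(self, t: int) -> int:
        i = int(np.searchsorted(self.times, t))
        if i >= len(self.times) or self.times[i] != t:
            raise KeyError(f"time {t} is not an active-window step")
        return i

    def position(self, tag: int, t: int) -> np.ndarray:
        return self.positions[tag, self.index_of(t)]

    def heading(self, tag: int, t: int) -> float:
        return float(self.headings[tag, self.index_of(t)])


def active_times(cfg: WorldConfig) -> np.ndarray:
    """All simulated time steps (s since epoch) inside active windows."""
    chunks = []
    for day in range(cfg.sim_days):
        base = day * 86400
        for (s, e) in sorted(cfg.active_windows):
            chunks.append(np.arange(base + s, base + e, cfg.time_step_s, dtype=np.int64))
    return np.concatenate(chunks)


def simulate_trajectories(cfg: WorldConfig, seed: int | None = None) -> TrajectorySet:
    """Simulate the movement model; identical output for identical seed/config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_tags
    nests = nest_positions(cfg.n_nests, cfg.nest_spacing_m, cfg.arena)
    nest_of = np.arange(n) % cfg.n_nests
    times = active_times(cfg)
    T = len(times)

    positions = np.empty((n, T, 2))
    headings = np.empty((n, T))

    attractor = nests[nest_of].copy()
    sd_target = np.full(n, cfg.home_sd_m)
    mode = np.full(n, _HOME, dtype=int)
    mode_until = np.zeros(n)
    offset = rng.standard_normal((n, 2)) * cfg.home_sd_m
    heading = rng.uniform(0.0, 2 * np.pi, n)

    arena = np.asarray(cfg.arena, dtype=float)
    prev_t = times[0]
    for k, t in enumerate(times):
        dt = float(t - prev_t) if k else 0.0
        prev_t = t

        if dt > 0:
            # end expired excursions
            expired = (mode != _HOME) & (t >= mode_until)
            if expired.any():
                mode[expired] = _HOME
                attractor[expired] = nests[nest_of[expired]]
                sd_target[expired] = cfg.home_sd_m

            # event draws (fixed-size draws keep the stream deterministic)
            u = rng.random(n)
            targets = rng.integers(0, max(n - 1, 1), n)
            flight_pts = rng.uniform(0.0, 1.0, (n, 2)) * arena
            p_perch = 1.0 - np.exp(-cfg.perch_rate_per_hour * dt / 3600.0)
            p_visit = 1.0 - np.exp(-cfg.visit_rate_per_hour * dt / 3600.0)
            p_flight = 1.0 - np.exp(-cfg.flight_rate_per_hour * dt / 3600.0)
            at_home = mode == _HOME
            start_perch = at_home & (u < p_perch)
            start_visit = at_home & ~start_perch & (u < p_perch + p_visit)
            start_flight = (
                at_home & ~start_perch & ~start_visit & (u < p_perch + p_visit + p_flight)
            )
            if start_perch.any():
                mode[start_perch] = _PERCH
                mode_until[start_perch] = t + cfg.perch_duration_s
                sd_target[start_perch] = cfg.perch_sd_m
            if start_visit.any():
                idx = np.flatnonzero(start_visit)
                tgt = targets[idx]
                tgt = tgt + (tgt >= idx)  # uniform over the other tags
                mode[idx] = _VISIT
                mode_until[idx] = t + cfg.visit_duration_s
                attractor[idx] = nests[nest_of[tgt]]
                sd_target[idx] = cfg.visit_sd_m
            if start_flight.any():
                mode[start_flight] = _FLIGHT
                mode_until[start_flight] = t + cfg.flight_duration_s
                attractor[start_flight] = flight_pts[start_flight]
                sd_target[start_flight] = cfg.flight_sd_m

            # exact OU update of the offset around the attractor
            a = np.exp(-dt / cfg.reversion_s)
            noise = rng.standard_normal((n, 2))
            offset = a * offset + np.sqrt(1.0 - a * a) * sd_target[:, None] * noise
            heading = heading + cfg.heading_turn_sd * np.sqrt(dt) * rng.standard_normal(n)

        # hard home-range cap keeps non-visiting tags strictly near their nest
        norm = np.linalg.norm(offset, axis=1)
        over = norm > cfg.max_home_range_m
        if over.any():
            offset[over] *= (cfg.max_home_range_m / norm[over])[:, None]

        pos = np.clip(attractor + offset, 0.0, arena)
        positions[:, k] = pos
        headings[:, k] = np.mod(heading, 2 * np.pi)

    return TrajectorySet(
        times=times,
        positions=positions,
        headings=headings,
        nest_of=nest_of,
        nests=nests,
        arena=cfg.arena,
    )


def true_contact_intervals(
    traj: TrajectorySet, dist_threshold_m: float = 5.0
) -> List[Dict]:
    """Ground-truth contact spans: contiguous steps with pairwise d < threshold.

    Used as the validation truth table for the reconstructed encounters.
    """
    out: List[Dict] = []
    times = traj.times
    step_gap = np.diff(times, prepend=times[0] - 1)
    n = traj.n_tags
    for a in range(n):
        for b in range(a + 1, n):
            d = np.linalg.norm(traj.positions[a] - traj.positions[b], axis=1)
            close = d < dist_threshold_m
            if not close.any():
                continue
            idx = np.flatnonzero(close)
            # break runs on index gaps or window boundaries
            breaks = np.flatnonzero(
                (np.diff(idx) > 1)
                | (step_gap[idx[1:]] > (times[1] - times[0] if len(times) > 1 else 1))
            )
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(idx) - 1]))
            for s, e in zip(starts, ends):
                seg = d[idx[s] : idx[e] + 1]
                out.append(
                    {
                        "tag_a": a,
                        "tag_b": b,
                        "start": int(times[idx[s]]),
                        "end": int(times[idx[e]]),
                        "min_dist_m": float(seg.min()),
                    }
                )
    return out
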
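"""ID-pulse generation: who hears which pulse, at what reported RSSI.

Every tag broadcasts an ID pulse every ``pulse_interval_s`` seconds during
active windows, with an unsynchronized per-tag phase.  Every other tag whose
expected RSSI at the current pairwise geometry is above the radio's reporting
floor receives a noisy, quantized detection; receiver stations log every
pulse within range (100 m by default) with no threshold.

Receiver stations also broadcast their clock every 15 minutes; those
broadcasts are emitted as detections with a receiver source id so the
firmware can model tag-clock synchronization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PropagationParams, TagConfig, WorldConfig
from .movement import TrajectorySet
from .propagation import expected_rssi, fold_angle, sample_rssi

__all__ = [
    "RECEIVER_ID_BASE",
    "receiver_layout",
    "generate_pulses",
]

#: listener/source ids >= this value denote receiver stations
RECEIVER_ID_BASE = 1000


def receiver_layout(cfg: WorldConfig) -> np.ndarray:
    """Receiver coordinates: configured positions, or a ring around the arena."""
    if cfg.receiver_positions is not None:
        pos = np.asarray(cfg.receiver_positions, dtype=float)
        if len(pos) != cfg.n_receivers:
            raise ValueError("receiver_positions length != n_receivers")
        return pos
    w, h = cfg.arena
    theta = 2 * np.pi * np.arange(cfg.n_receivers) / max(cfg.n_receivers, 1)
    return np.column_stack(
        (w / 2 + 0.45 * w * np.cos(theta), h / 2 + 0.45 * h * np.sin(theta))
    )


def _rel_angle_to_receiver(headings: np.ndarray) -> np.ndarray:
    # receiver antennae are fixed; misalignment is the tag heading folded
    return fold_angle(headings)


def generate_pulses(
    traj: TrajectorySet,
    cfg: WorldConfig,
    p: PropagationParams,
    pulse_interval_s: int = 20,
    rng: np.random.Generator | None = None,
    tag_cfg: TagConfig | None = None,
) -> pd.DataFrame:
    """Simulate the full detection stream for one deployment.

    Returns a time-sorted DataFrame with columns ``listener_id, source_id,
    t, rssi`` (all integers).  Tag-tag rows are emitted only when the
    expected RSSI is above the reporting floor ``p.rssi_min`` (fainter pulses
    are below the radio's sensitivity); tag-receiver rows whenever the tag is
    within receiver range; receiver-clock broadcasts (source id >=
    :data:`RECEIVER_ID_BASE`) whenever a tag is in range at a 15-minute mark.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    if pulse_interval_s <= 0:
        raise ValueError("pulse_interval_s must be positive")
    step = int(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else 1
    if pulse_interval_s % step != 0:
        raise ValueError("time step must divide pulse_interval_s")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tag_cfg = tag_cfg or TagConfig(pulse_interval_s=pulse_interval_s)

    n = traj.n_tags
    times = traj.times
    receivers = receiver_layout(cfg)

    # unsynchronized per-tag pulse phases on the step grid
    phases = rng.integers(0, pulse_interval_s // step, n) * step

    frames = []
    for src in range(n):
        sel = np.flatnonzero((times % pulse_interval_s) == phases[src])
        if len(sel) == 0:
            continue
        t_p = times[sel]
        pos_s = traj.positions[src, sel]
        head_s = traj.headings[src, sel]

        for lst in range(n):
            if lst == src:
                continue
            d = np.linalg.norm(traj.positions[lst, sel] - pos_s, axis=1)
            ang = head_s - traj.headings[lst, sel]
            mu = expected_rssi(d, ang, "body", p)
            audible = mu >= p.rssi_min
            if not audible.any():
                continue
            rssi = sample_rssi(mu[audible], p, rng, d[audible])
            frames.append(
                pd.DataFrame(
                    {
                        "listener_id": lst,
                        "source_id": src,
                        "t": t_p[audible],
                        "rssi": rssi,
                    }
                )
            )

        for r in range(len(receivers)):
            d = np.linalg.norm(receivers[r] - pos_s, axis=1)
            in_range = d <= tag_cfg.receiver_range_m
            if not in_range.any():
                continue
            mu = (
                expected_rssi(d[in_range], _rel_angle_to_receiver(head_s[in_range]), "body", p)
                + p.receiver_gain
            )
            rssi = sample_rssi(mu, p, rng, d[in_range])
            frames.append(
                pd.DataFrame(
                    {
                        "listener_id": RECEIVER_ID_BASE + r,
                        "source_id": src,
                        "t": t_p[in_range],
                        "rssi": rssi,
                    }
                )
            )

    # receiver clock broadcasts to tags in range
    sync_marks = times[(times % tag_cfg.receiver_sync_period_s) == 0]
    if len(sync_marks):
        sel = np.searchsorted(times, sync_marks)
        for r in range(len(receivers)):
            d = np.linalg.norm(traj.positions[:, sel, :] - receivers[r], axis=2)  # (n, K)
            for lst in range(n):
                in_range = d[lst] <= tag_cfg.receiver_range_m
                if not in_range.any():
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "listener_id": lst,
                            "source_id": RECEIVER_ID_BASE + r,
                            "t": sync_marks[in_range],
                            "rssi": 0,
                        }
                    )
                )

    if not frames:
        return pd.DataFrame(columns=["listener_id", "source_id", "t", "rssi"]).astype(int)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["t", "source_id", "listener_id"], kind="mergesort").reset_index(
        drop=True
    )
    return out.astype({"listener_id": int, "source_id": int, "t": int, "rssi": int})
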
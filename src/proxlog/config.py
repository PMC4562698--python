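"""Configuration objects for the proximity-logger simulator and pipeline.

Every tunable of the system lives in one of four dataclasses:

* :class:`WorldConfig` -- the deployment layout and the movement model of the
  tagged animals (arena, nests, receivers, daily sampling windows).
* :class:`PropagationParams` -- the RSSI-versus-distance/orientation model,
  including measurement noise, quantization limits and the body-mount gain.
* :class:`TagConfig` -- the tag firmware settings (pulse interval, detection
  threshold, encounter cap, memory, clocks, battery).
* :class:`PipelineConfig` -- thresholds of the downstream log-reconciliation
  pipeline and the RSSI cut-offs used for network construction.

:class:`RunConfig` bundles the four plus a master seed and supports a YAML
round-trip so a whole run is reproducible from a single file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml

__all__ = [
    "PropagationParams",
    "WorldConfig",
    "TagConfig",
    "PipelineConfig",
    "RunConfig",
    "derive_seed",
]

# Log-distance coefficients solved from the two distance anchors used for
# network thresholds: RSSI 0 at 5 m and RSSI 40 at 0.1 m (body mount, parallel
# antennae).  slope = -40 / log10(5 / 0.1); reference = -slope * log10(5).
_SLOPE_PER_DECADE = -40.0 / math.log10(50.0)  # ~ -23.544 RSSI per decade
_BODY_REF_1M = -_SLOPE_PER_DECADE * math.log10(5.0)  # ~ +16.456 RSSI at 1 m


@dataclass
class PropagationParams:
    """RSSI propagation model.

    Expected RSSI at distance ``d`` (m), relative antenna angle ``a`` and
    mount ``m`` is::

        rssi_at_ref + slope_per_log10m * log10(max(d, d_min_clamp))
            + mount_gain * [m == body]
            - orientation_penalty_max * (1 - exp(-d / orientation_ramp_m)) * |sin a|

    Reported values carry Gaussian noise whose standard deviation grows with
    distance, ``noise_sd * (1 + d / noise_distance_scale_m)``, and are rounded
    to integers and clipped to ``[rssi_min, rssi_max]`` (the radio's reporting
    range; -17..57 was the observed span in the field).
    """

    rssi_at_ref: float = _BODY_REF_1M - 6.0   # bare tag at 1 m
    slope_per_log10m: float = _SLOPE_PER_DECADE
    orientation_penalty_max: float = 19.0
    orientation_ramp_m: float = 0.13
    mount_gain: float = 6.0                   # animal / saline body amplification
    receiver_gain: float = 14.0               # receiver-station antenna advantage
    noise_sd: float = 2.2                     # sd at contact
    noise_distance_scale_m: float = 10.0      # sd(d) = noise_sd * (1 + d/scale)
    rssi_min: int = -17
    rssi_max: int = 57
    d_min_clamp: float = 0.02

    def validate(self) -> None:
        if not self.slope_per_log10m < 0:
            raise ValueError("slope_per_log10m must be negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.rssi_min < self.rssi_max:
            raise ValueError("rssi_min must be < rssi_max")
        if not self.d_min_clamp > 0:
            raise ValueError("d_min_clamp must be > 0")
        if self.orientation_ramp_m <= 0:
            raise ValueError("orientation_ramp_m must be > 0")


@dataclass
class WorldConfig:
    """Deployment layout and animal movement model.

    Tags follow a mean-reverting (Ornstein-Uhlenbeck) walk around their
    assigned nest, interrupted by three kinds of excursion: *perch* bouts
    tight on the nest (body-contact range for nest mates), *visits* to
    another tag's nest (the social-contact generator) and *flights* to a
    random point in the arena.  Event rates are per-hour Poisson rates.
    """

    n_tags: int = 17
    sim_days: int = 3
    # seconds-of-day windows; the deployment sampled 6-9 am and 5-8 pm
    active_windows: Tuple[Tuple[int, int], ...] = (
        (6 * 3600, 9 * 3600),
        (17 * 3600, 20 * 3600),
    )
    time_step_s: int = 5
    arena: Tuple[float, float] = (60.0, 36.0)  # meters
    n_nests: int = 9
    nest_spacing_m: float = 8.0
    n_receivers: int = 8
    receiver_positions: Optional[Tuple[Tuple[float, float], ...]] = None
    seed: int = 0
    # movement knobs
    home_sd_m: float = 1.0
    max_home_range_m: float = 5.0
    reversion_s: float = 10.0
    visit_rate_per_hour: float = 2.0
    visit_duration_s: float = 90.0
    visit_sd_m: float = 0.4
    flight_rate_per_hour: float = 4.0
    flight_duration_s: float = 20.0
    flight_sd_m: float = 2.0
    perch_rate_per_hour: float = 6.0
    perch_duration_s: float = 120.0
    perch_sd_m: float = 0.05
    heading_turn_sd: float = 0.1  # rad / sqrt(s); orientation persists across pulse slots

    def validate(self) -> None:
        if self.n_tags < 2:
            raise ValueError("n_tags must be >= 2")
        if self.sim_days < 1:
            raise ValueError("sim_days must be >= 1")
        if self.time_step_s < 1:
            raise ValueError("time_step_s must be a positive integer")
        if self.n_nests < 1:
            raise ValueError("n_nests must be >= 1")
        windows = sorted(self.active_windows)
        for (s, e) in windows:
            if not (0 <= s < e <= 86400):
                raise ValueError(f"bad active window ({s}, {e})")
        for (_, e1), (s2, _) in zip(windows, windows[1:]):
            if s2 < e1:
                raise ValueError("active windows overlap within a day")
        grid = _nest_grid(self.n_nests, self.nest_spacing_m)
        span_x = grid[:, 0].max() - grid[:, 0].min()
        span_y = grid[:, 1].max() - grid[:, 1].min()
        if span_x > self.arena[0] or span_y > self.arena[1]:
            raise ValueError("arena too small for nest spacing")


def _nest_grid(n_nests: int, spacing: float):
    """Nest coordinates on a square grid with the given spacing (origin-based)."""
    import numpy as np

    cols = int(math.ceil(math.sqrt(n_nests)))
    pts = []
    for k in range(n_nests):
        i, j = k % cols, k // cols
        pts.append((i * spacing, j * spacing))
    return np.asarray(pts, dtype=float)


def nest_positions(n_nests: int, spacing: float, arena: Tuple[float, float]):
    """Nest grid centered within the arena."""
    grid = _nest_grid(n_nests, spacing)
    lo = grid.min(axis=0)
    hi = grid.max(axis=0)
    import numpy as np

    center = (np.asarray(arena, dtype=float) - (hi - lo)) / 2.0
    return grid - lo + center


@dataclass
class TagConfig:
    """Tag firmware settings (field-deployment defaults)."""

    pulse_interval_s: int = 20
    detection_threshold_rssi: int = 0
    max_encounter_s: int = 300
    max_concurrent: int = 30
    memory_capacity: int = 300
    clock_saver_period_s: int = 30
    battery_life_s: Optional[float] = None      # None = outlasts the run
    clock_drift_s_per_day: float = 2.0
    reset_interval_s: float = 600.0             # mean time between post-battery resets
    receiver_range_m: float = 100.0
    receiver_sync_period_s: int = 900           # receivers broadcast clock every 15 min
    download_flush_time_s: int = 85800          # 23:50 daily memory download window

    def validate(self) -> None:
        for name in (
            "pulse_interval_s",
            "max_encounter_s",
            "max_concurrent",
            "memory_capacity",
            "clock_saver_period_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_encounter_s % self.pulse_interval_s != 0:
            raise ValueError("max_encounter_s must be a multiple of pulse_interval_s")


@dataclass
class PipelineConfig:
    """Log-reconciliation thresholds and network RSSI cut-offs."""

    merge_gap_s: int = 20      # combine same-pair logs separated by <= one pulse
    break_gap_s: int = 21      # broken: other side has an internal gap > this
    stagger_s: int = 21        # staggered: one side overhangs by > this
    network_thresholds: Tuple[int, ...] = (0, 40)

    def validate(self) -> None:
        if self.merge_gap_s < 0 or self.break_gap_s < 0 or self.stagger_s < 0:
            raise ValueError("pipeline thresholds must be non-negative")


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    propagation: PropagationParams = field(default_factory=PropagationParams)
    tag: TagConfig = field(default_factory=TagConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    out_dir: str = "proxlog_out"

    def validate(self) -> None:
        self.world.validate()
        self.propagation.validate()
        self.tag.validate()
        self.pipeline.validate()
        if self.tag.pulse_interval_s % self.world.time_step_s != 0:
            raise ValueError("time_step_s must divide pulse_interval_s")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "world": dataclasses.asdict(self.world),
            "propagation": dataclasses.asdict(self.propagation),
            "tag": dataclasses.asdict(self.tag),
            "pipeline": dataclasses.asdict(self.pipeline),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, key):
            sub = dict(d.get(key) or {})
            known = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - known
            if bad:
                raise ValueError(f"unknown key(s) under '{key}': {sorted(bad)}")
            for name in list(sub):
                if isinstance(sub[name], list):
                    sub[name] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in sub[name]
                    )
            return klass(**sub)

        cfg = cls(
            world=build(WorldConfig, "world"),
            propagation=build(PropagationParams, "propagation"),
            tag=build(TagConfig, "tag"),
            pipeline=build(PipelineConfig, "pipeline"),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "proxlog_out")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.blake2s(self.to_yaml().encode(), digest_size=6).hexdigest()


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-component seed derived from one master seed (< 2**31)."""
    h = hashlib.blake2s(f"{master_seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)
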
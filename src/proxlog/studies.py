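"""Canonical study configurations used for validation and reporting.

Each function returns a ready :class:`~proxlog.config.RunConfig` describing
one named study condition.  Keeping them here (rather than scattered through
tests and scripts) makes the conditions part of the package contract:

* :func:`reciprocity_study` -- the idealized mutual-radio-range colony used
  to verify that the reconciliation pipeline introduces no artifacts of its
  own: noiseless radio, detection threshold at the sensitivity floor, no
  clock drift, healthy batteries, and an arena small enough that every tag
  hears every pulse of every other tag.  Under these conditions every
  encounter record must be dyadic with no broken or staggered flags.
* :func:`quality_study` -- the field-like condition used for the
  direction-of-effect analyses: default radio noise, 0-RSSI detection
  threshold, a colony of nest pairs with social visits, so that single logs
  arise from threshold censoring and phase mismatch and broken logs from
  distance-driven dropouts.
* :func:`deployment_study` -- a small version of the full deployment layout
  (17 tags, morning/evening windows) for end-to-end runs and network
  construction.
"""

from __future__ import annotations

from .config import RunConfig

__all__ = ["reciprocity_study", "quality_study", "deployment_study"]


def reciprocity_study(seed: int = 0, n_tags: int = 17, duration_s: int = 3600) -> RunConfig:
    """Noiseless, threshold-free, all-in-range colony (one compressed hour)."""
    cfg = RunConfig(seed=seed)
    cfg.world.n_tags = n_tags
    cfg.world.sim_days = 1
    cfg.world.active_windows = ((0, duration_s),)
    # arena diagonal < 4.1 m keeps even perpendicular pairs above the
    # reporting floor, so every pulse is heard by every tag
    cfg.world.arena = (2.8, 2.8)
    cfg.world.n_nests = 1
    cfg.world.nest_spacing_m = 1.0
    cfg.world.max_home_range_m = 2.0
    cfg.propagation.noise_sd = 0.0
    cfg.tag.detection_threshold_rssi = cfg.propagation.rssi_min
    cfg.tag.clock_drift_s_per_day = 0.0
    cfg.validate()
    return cfg


def quality_study(seed: int = 0, n_tags: int = 14, duration_s: int = 10800) -> RunConfig:
    """Field-like colony for log-reliability analyses (threshold censoring on)."""
    cfg = RunConfig(seed=seed)
    cfg.world.n_tags = n_tags
    cfg.world.sim_days = 1
    cfg.world.active_windows = ((0, duration_s),)
    cfg.world.n_nests = max(n_tags // 2, 2)
    cfg.world.nest_spacing_m = 8.0
    cfg.world.arena = (34.0, 24.0)
    cfg.world.visit_rate_per_hour = 6.0
    cfg.world.visit_duration_s = 90.0
    cfg.validate()
    return cfg


def deployment_study(seed: int = 0, sim_days: int = 1) -> RunConfig:
    """Downscaled full deployment: 17 tags, 6-9 am / 5-8 pm windows."""
    cfg = RunConfig(seed=seed)
    cfg.world.sim_days = sim_days
    cfg.world.visit_rate_per_hour = 4.0
    cfg.validate()
    return cfg
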
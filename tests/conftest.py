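import numpy as np
import pandas as pd
import pytest

import proxlog as px


@pytest.fixture(scope="session")
def params():
    return px.PropagationParams()


@pytest.fixture(scope="session")
def reciprocity_run():
    """Noiseless all-in-range colony run, shared across tests."""
    cfg = px.reciprocity_study(seed=7)
    sim = px.simulate_deployment(cfg, with_truth=False)
    rec = px.process_logs(sim.logs, cfg.pipeline, uptime=sim.uptime)
    return cfg, sim, rec


@pytest.fixture(scope="session")
def quality_run():
    """One field-like colony run with threshold censoring, shared."""
    cfg = px.quality_study(seed=0)
    sim = px.simulate_deployment(cfg, with_truth=False)
    rec = px.process_logs(sim.logs, cfg.pipeline, uptime=sim.uptime)
    return cfg, sim, rec


@pytest.fixture()
def two_tag_pulses():
    """Deterministic stream: two tags exchanging pulses at 1 m for 60 s."""
    rows = []
    for t in (0, 20, 40):
        rows.append((0, 1, t, 10))
        rows.append((1, 0, t, 10))
    return pd.DataFrame(rows, columns=["listener_id", "source_id", "t", "rssi"]).sort_values(
        "t", kind="mergesort"
    ).reset_index(drop=True)


def make_logs(rows):
    """Raw encounter-log frame from (logger, partner, start, end, min, mean, max, n)."""
    return pd.DataFrame(
        rows,
        columns=["logger_id", "partner_id", "start", "end",
                 "min_rssi", "mean_rssi", "max_rssi", "n_pulses"],
    )
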
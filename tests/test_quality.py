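import numpy as np
import pandas as pd
import pytest

import proxlog as px
from _oracles import frames_from_fragments


def dyad_records(n, rng=None, noise_sd=0.0):
    """Synthetic dyadic record table with optional per-side noise."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for k in range(n):
        base_max, base_min, base_mean = 20.0, 5.0, 12.0
        dur = 40 + 20 * (k % 5)
        start = 1000 * k
        rec = {
            "pair_id": "1-2", "tag_a": 1, "tag_b": 2, "status": "dyadic",
            "start": start, "end": start + dur, "duration": dur,
            "broken": False, "staggered": False,
            "n_fragments_a": 1, "n_fragments_b": 1,
        }
        for side in ("a", "b"):
            eps = rng.normal(0, noise_sd, 3)
            rec[f"max_rssi_{side}"] = base_max + eps[0]
            rec[f"min_rssi_{side}"] = base_min + eps[1]
            rec[f"mean_rssi_{side}"] = base_mean + eps[2]
            rec[f"start_{side}"] = start
            rec[f"end_{side}"] = start + dur
            rec[f"n_pulses_{side}"] = dur // 20 + 1
        rec["max_rssi"] = max(rec["max_rssi_a"], rec["max_rssi_b"])
        rec["min_rssi"] = min(rec["min_rssi_a"], rec["min_rssi_b"])
        rec["mean_rssi"] = (rec["mean_rssi_a"] + rec["mean_rssi_b"]) / 2
        rows.append(rec)
    return pd.DataFrame(rows)


class TestReciprocityStats:
    def test_static_noiseless_pair_perfectly_reciprocal(self):
        """Constant geometry, no noise: both sides log identical statistics."""
        import pandas as pd
        from proxlog.config import TagConfig
        from proxlog.firmware import run_deployment

        rows = []
        for lo, hi in ((0, 280), (400, 580)):  # two bouts > 20 s apart
            for t in range(lo + 2, hi, 20):    # tag 0 hears tag 1 at phase 2
                rows.append((0, 1, t, 10))
            for t in range(lo + 10, hi, 20):   # tag 1 hears tag 0 at phase 10
                rows.append((1, 0, t, 10))
        pulses = pd.DataFrame(
            rows, columns=["listener_id", "source_id", "t", "rssi"]
        ).sort_values("t", kind="mergesort").reset_index(drop=True)
        res = run_deployment(pulses, TagConfig(clock_drift_s_per_day=0.0), sim_span=(0, 600))
        rec = px.process_logs(res.logs)
        assert list(rec.status) == ["dyadic", "dyadic"]
        table = px.reciprocity_stats(rec)
        assert len(table) == 4
        assert (table["mean_abs_diff"] == 0).all()

    def test_colony_run_reciprocity_bounded_by_phase(self, reciprocity_run):
        """Noiseless colony: side disagreements stem only from unsynchronized
        pulse phases, so duration differences stay below one pulse interval."""
        _, _, rec = reciprocity_run
        table = px.reciprocity_stats(rec)
        assert set(table.index) == {"max_rssi", "min_rssi", "mean_rssi", "duration"}
        assert table.loc["duration", "max_abs_diff"] < 20
        assert (table["n"] == (rec.status == "dyadic").sum()).all()

    def test_folded_normal_difference_of_noisy_sides(self):
        """|A - B| with independent N(0,3) noise per side has mean 3*sqrt(2)*sqrt(2/pi)."""
        rec = dyad_records(4000, np.random.default_rng(5), noise_sd=3.0)
        table = px.reciprocity_stats(rec)
        expected = 3.0 * np.sqrt(2.0) * np.sqrt(2.0 / np.pi)
        for m in ("max_rssi", "min_rssi", "mean_rssi"):
            assert table.loc[m, "mean_abs_diff"] == pytest.approx(expected, rel=0.06)

    def test_invariant_to_side_swap(self):
        rec = dyad_records(50, np.random.default_rng(1), noise_sd=2.0)
        swapped = rec.copy()
        for m in ("max_rssi", "min_rssi", "mean_rssi", "start", "end", "n_pulses"):
            swapped[f"{m}_a"], swapped[f"{m}_b"] = rec[f"{m}_b"], rec[f"{m}_a"]
        t1 = px.reciprocity_stats(rec)
        t2 = px.reciprocity_stats(swapped)
        pd.testing.assert_series_equal(t1["mean_abs_diff"], t2["mean_abs_diff"])

    def test_too_few_dyads_warns_empty(self):
        rec = dyad_records(1)
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = px.reciprocity_stats(rec)
        assert table.empty


class TestFitDyadProbability:
    def test_duration_raises_dyad_odds_in_simulation(self, quality_run):
        _, _, rec = quality_run
        model = px.fit_dyad_probability(rec)
        assert model.loc["duration", "coef"] > 0
        assert model.attrs["note"] == "ml"

    def test_constant_predictor_excluded(self):
        rec = dyad_records(40, np.random.default_rng(2), noise_sd=1.0)
        rec.loc[::2, "status"] = "single"
        rec["min_rssi"] = 5.0
        with pytest.warns(UserWarning, match="min_rssi.*constant"):
            model = px.fit_dyad_probability(rec)
        assert "min_rssi" not in model.index

    def test_single_status_rejected(self):
        rec = dyad_records(10)
        with pytest.raises(ValueError, match="both dyadic and single"):
            px.fit_dyad_probability(rec)

    def test_null_predictors_rarely_significant(self):
        """Outcome independent of predictors: |Wald z| < 3 nearly always."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(30):
            rec = dyad_records(200, rng, noise_sd=3.0)
            rec.loc[rng.random(200) < 0.5, "status"] = "single"
            model = px.fit_dyad_probability(rec)
            z = model.drop(index="const")["wald_z"].abs()
            hits += int((z < 3).all())
        assert hits >= 27


class TestBrokenMatching:
    def make(self, broken_durs, unbroken_durs):
        rec = dyad_records(len(broken_durs) + len(unbroken_durs))
        durs = list(broken_durs) + list(unbroken_durs)
        rec["duration"] = durs
        rec["end"] = rec["start"] + rec["duration"]
        rec["broken"] = [True] * len(broken_durs) + [False] * len(unbroken_durs)
        return rec

    def test_nearest_duration_wins(self):
        rec = self.make([100], [95, 300])
        m = px.match_broken_logs(rec)
        assert len(m["matched"]) == 1
        assert rec.loc[m["matched"].iloc[0]["unbroken_idx"], "duration"] == 95

    def test_tie_broken_by_earlier_start(self):
        rec = self.make([100], [90, 110])
        m = px.match_broken_logs(rec)
        chosen = rec.loc[m["matched"].iloc[0]["unbroken_idx"]]
        assert chosen["duration"] == 90  # equal |diff|; earlier start wins

    def test_surplus_broken_reported_unmatched(self):
        rec = self.make([100, 100, 100], [95])
        m = px.match_broken_logs(rec)
        assert len(m["matched"]) == 1 and len(m["unmatched_broken"]) == 2

    def test_matching_beats_random_pairing(self):
        rng = np.random.default_rng(3)
        rec = self.make(list(rng.integers(0, 300, 30)), list(rng.integers(0, 300, 60)))
        m = px.match_broken_logs(rec)
        greedy = m["mean_duration_diff"]
        b = rec.loc[rec.broken, "duration"].to_numpy()
        u = rec.loc[~rec.broken, "duration"].to_numpy()
        randoms = [
            np.abs(b - rng.permutation(u)[: len(b)]).mean() for _ in range(100)
        ]
        assert greedy <= min(randoms)

    def test_requires_both_groups(self):
        rec = self.make([100], [])
        with pytest.raises(ValueError, match="broken and one unbroken"):
            px.match_broken_logs(rec)


class TestBrokenVsUnbrokenSummary:
    def test_identical_groups_zero_differences(self):
        rec = dyad_records(20)
        rec.loc[:9, "broken"] = True
        summ = px.broken_vs_unbroken_summary(px.match_broken_logs(rec))
        assert (summ["broken_mean"] == summ["unbroken_mean"]).all()

    def test_single_pulse_record_has_zero_spread(self):
        rec = dyad_records(4)
        rec.loc[:1, "broken"] = True
        rec["max_rssi"] = rec["min_rssi"] = 7
        summ = px.broken_vs_unbroken_summary(px.match_broken_logs(rec))
        assert summ.loc["spread", ["broken_mean", "unbroken_mean"]].eq(0).all()

    def test_simulated_broken_logs_sit_at_lower_rssi(self, quality_run):
        """Distance-driven dropouts put broken records farther (weaker RSSI)."""
        _, _, rec = quality_run
        summ = px.broken_vs_unbroken_summary(px.match_broken_logs(rec))
        for m in ("max_rssi", "min_rssi", "mean_rssi"):
            assert summ.loc[m, "broken_mean"] < summ.loc[m, "unbroken_mean"]
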
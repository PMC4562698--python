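import dataclasses

import numpy as np
import pandas as pd
import pytest

import proxlog as px


@pytest.fixture(scope="module")
def tag_trials(params):
    return px.simulate_calibration(params, seed=0)


class TestSimulateCalibration:
    def test_design_shape(self, tag_trials):
        # 11 pairs x 7 distances x 2 orientations x 3 replicates
        assert len(tag_trials) == 11 * 7 * 2 * 3
        counts = tag_trials.groupby(["pair_id", "distance_m", "orientation"]).size()
        assert (counts == 3).all()

    def test_rssi_within_reporting_range(self, tag_trials, params):
        assert tag_trials.rssi.between(params.rssi_min, params.rssi_max).all()

    def test_body_mounts_read_higher_than_pole(self, params):
        pole = px.simulate_calibration(params, mounts=("pole",), seed=1)
        saline = px.simulate_calibration(params, mounts=("saline",), seed=1)
        sel = pole.distance_m.between(0.1, 2.0)
        assert saline.loc[sel, "rssi"].mean() > pole.loc[sel, "rssi"].mean() + 3


class TestFitPropagation:
    def test_recovers_slope_within_2se(self, params):
        p = dataclasses.replace(params, rssi_min=-90)  # repeater-mode bench
        fit = px.fit_propagation(px.simulate_calibration(p, seed=3))
        err = abs(fit.slope_per_log10m - params.slope_per_log10m)
        assert err <= 2 * fit.slope_se
        assert fit.slope_per_log10m < 0

    def test_near_zero_noise_recovers_coefficients(self, params):
        p = dataclasses.replace(params, noise_sd=0.05, rssi_min=-90)
        fit = px.fit_propagation(px.simulate_calibration(p, pair_sd=0.0, seed=4))
        assert fit.slope_per_log10m == pytest.approx(p.slope_per_log10m, rel=0.005)
        assert fit.table_log.loc["Intercept", "coef"] == pytest.approx(
            p.rssi_at_ref + p.mount_gain, abs=0.5
        )

    def test_orientation_effect_negative(self, params):
        fit = px.fit_propagation(px.simulate_calibration(params, seed=5))
        assert fit.table_log.loc["perp", "coef"] < 0
        assert fit.table_linear.loc["perp", "coef"] < 0

    def test_singular_designs_rejected(self, params):
        df = px.simulate_calibration(params, distances=(1.0,), seed=0)
        with pytest.raises(ValueError, match="singular"):
            px.fit_propagation(df)
        df1 = px.simulate_calibration(params, n_pairs=1, seed=0)
        with pytest.raises(ValueError, match="pairs"):
            px.fit_propagation(df1)


class TestDiscriminability:
    def test_default_set_confuses_only_5m_and_10m(self, tag_trials):
        disc = px.distance_bin_discriminability(tag_trials)
        fuzzy = disc.loc[~disc["distinct"], ["d1_m", "d2_m"]]
        assert [(r.d1_m, r.d2_m) for r in fuzzy.itertuples()] == [(5.0, 10.0)]

    def test_identical_bins_flagged(self, params):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 3, 60)
        df = pd.DataFrame({
            "distance_m": np.repeat([1.0, 2.0], 60),
            "rssi": np.concatenate([vals, vals]),
        })
        disc = px.distance_bin_discriminability(df)
        assert not disc.iloc[0]["distinct"]

    def test_well_separated_bins_not_flagged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "distance_m": np.repeat([1.0, 2.0], 60),
            "rssi": np.concatenate([rng.normal(30, 2, 60), rng.normal(0, 2, 60)]),
        })
        disc = px.distance_bin_discriminability(df)
        assert disc["distinct"].all()

    def test_separation_shrinks_with_bin_spacing(self, params):
        """Closer bins (relative to noise) score lower standardized separation."""
        rng = np.random.default_rng(2)

        def score(gap):
            df = pd.DataFrame({
                "distance_m": np.repeat([1.0, 2.0], 80),
                "rssi": np.concatenate(
                    [rng.normal(0, 3, 80), rng.normal(-gap, 3, 80)]
                ),
            })
            return abs(px.distance_bin_discriminability(df).iloc[0]["cohen_d"])

        scores = [score(g) for g in (20, 10, 5, 2)]
        assert scores == sorted(scores, reverse=True)


class TestInferDistanceBin:
    @pytest.mark.parametrize("rssi,label", [(45, "<0.1m"), (40, "<0.1m"),
                                            (3, "<5m"), (0, "<5m"), (-10, ">=5m")])
    def test_threshold_binning(self, rssi, label):
        assert px.infer_distance_bin(rssi)[0] == label

    def test_monotone_in_rssi(self):
        order = {"<0.1m": 0, "<5m": 1, ">=5m": 2}
        labels = [order[px.infer_distance_bin(r)[0]] for r in range(-17, 58)]
        assert labels == sorted(labels, reverse=True)

    def test_likelihood_profile_never_a_point_distance(self, params):
        fit = px.fit_propagation(px.simulate_calibration(params, seed=6))
        label, profile = px.infer_distance_bin(45, fit)
        assert label == "<0.1m"
        assert set(profile.columns) == {"bin", "likelihood"}
        assert profile["likelihood"].sum() == pytest.approx(1.0)


class TestReceiverVariability:
    def test_cv_larger_at_10m_than_1m(self, params):
        recv = px.simulate_receiver_calibration(params, seed=0)
        rv = px.receiver_variability(recv)
        cv = rv["cv"].set_index("distance_m")["cv"]
        assert cv[10.0] > cv[1.0] > 0

    def test_identical_noiseless_receivers_cv_zero(self, params):
        p = dataclasses.replace(params, noise_sd=0.0)
        recv = px.simulate_receiver_calibration(
            p, receiver_bias_sd=0.0, orientations=("parallel",), seed=0
        )
        rv = px.receiver_variability(recv)
        assert (rv["cv"]["sd_rssi"] == 0).all()
        assert not rv["pairwise"]["different"].any()

    def test_offset_receiver_pair_flagged(self, params):
        p = dataclasses.replace(params, noise_sd=1.0)
        recv = px.simulate_receiver_calibration(
            p, n_receivers=2, receiver_bias_sd=0.0, n_reps=12, seed=1
        )
        recv.loc[recv.pair_id == "R1", "rssi"] += 10
        rv = px.receiver_variability(recv)
        assert rv["pairwise"].iloc[0]["different"]

    def test_single_receiver_rejected(self, params):
        recv = px.simulate_receiver_calibration(params, n_receivers=1, seed=0)
        with pytest.raises(ValueError, match="single receiver"):
            px.receiver_variability(recv)
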
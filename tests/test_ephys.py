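"""Background statistics, 2-SD threshold rule, tuning curves, group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bladderkit import ephys
from bladderkit.synthetic import EvokedSimParams, simulate_evoked_dataset

LEVELS = list(range(100, 155, 3))


def dataset_from_level_means(means_by_level, background, n_reps=8,
                             frequency=95):
    """Deterministic dataset whose per-level means are given exactly."""
    rows = [(frequency, lv, rep + 1, means_by_level[lv])
            for lv in LEVELS for rep in range(n_reps)]
    trials = pd.DataFrame(rows, columns=["frequency_hz", "level_db", "rep",
                                         "magnitude_uv"])
    return ephys.EvokedDataset(background=np.asarray(background), trials=trials)


class TestBackgroundStats:
    def test_constant(self):
        assert ephys.background_stats([1, 1, 1, 1]) == (1.0, 0.0)

    def test_two_values(self):
        mu, sd = ephys.background_stats([0.0, 2.0])
        assert mu == 1.0
        assert sd == pytest.approx(np.sqrt(2))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 0.7, 10_000)
        mu, sd = ephys.background_stats(x)
        assert mu == pytest.approx(3.0, rel=0.02)
        assert sd == pytest.approx(0.7, rel=0.02)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ephys.background_stats([1.0])


class TestDetermineThreshold:
    background = [0.5, 1.5, 1.0, 1.0]  # mean 1.0, criterion scans against 2 SD

    def test_brute_force_scan(self):
        """Lowest level whose mean exceeds mean + 2 SD: oracle by direct scan."""
        bg = np.array([1.0, 1.0, 0.5, 1.5])        # mean 1, sd ~ 0.408
        mu, sd = np.mean(bg), np.std(bg, ddof=1)
        means = {lv: (1.0 if lv < 121 else 2.5) for lv in LEVELS}
        ds = dataset_from_level_means(means, bg)
        # independent oracle: linear scan of the grid
        expected = min(lv for lv in LEVELS if means[lv] >= mu + 2 * sd)
        assert ephys.determine_threshold(ds, 95) == expected == 121

    def test_no_response(self):
        ds = dataset_from_level_means({lv: 1.0 for lv in LEVELS},
                                      [1.0, 1.0, 0.5, 1.5])
        assert np.isnan(ephys.determine_threshold(ds, 95))

    def test_boundary_is_inclusive(self):
        """'At least two standard deviations above' counts exact equality."""
        bg = [1.0, 1.0, 0.5, 1.5]
        crit = np.mean(bg) + 2 * np.std(bg, ddof=1)
        means = {lv: (0.0 if lv < 130 else crit) for lv in LEVELS}
        ds = dataset_from_level_means(means, bg)
        assert ephys.determine_threshold(ds, 95) == 130

    def test_missing_levels_reported(self):
        ds = dataset_from_level_means({lv: 1.0 for lv in LEVELS}, [1.0, 2.0])
        ds.trials = ds.trials[ds.trials["level_db"] != 115]
        with pytest.raises(ValueError, match="no trials"):
            ephys.determine_threshold(ds, 190)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(bump=st.floats(0.0, 5.0))
    def test_monotone_in_magnitude(self, bump):
        """Raising every magnitude can only lower (or keep) the threshold."""
        p = EvokedSimParams(true_threshold=130.0, seed=11)
        ds = simulate_evoked_dataset(p, frequencies=[95], levels=LEVELS)
        base = ephys.determine_threshold(ds, 95)
        boosted = ephys.EvokedDataset(
            background=ds.background,
            trials=ds.trials.assign(
                magnitude_uv=ds.trials["magnitude_uv"] + bump))
        new = ephys.determine_threshold(boosted, 95)
        if np.isnan(base):
            return
        assert np.isnan(new) or new <= base


class TestTuningCurve:
    def test_flat_recovery(self):
        p = EvokedSimParams(true_threshold=121.0, growth_slope=2.0,
                            background_sd=0.05, saturation_level=60.0, seed=0)
        ds = simulate_evoked_dataset(p)
        curve = ephys.tuning_curve(ds)
        assert np.nanmax(np.abs(curve.thresholds - 121.0)) <= 3.0

    def test_zero_snr_all_no_response(self):
        p = EvokedSimParams(growth_slope=0.0, seed=4)
        ds = simulate_evoked_dataset(p)
        curve = ephys.tuning_curve(ds)
        # with zero signal, qualifying by chance at any frequency is rare
        assert np.isnan(curve.thresholds).mean() > 0.7

    def test_group_curve_reports_ci_and_n(self):
        curves = []
        for seed in range(5):
            p = EvokedSimParams(true_threshold=130.0, growth_slope=1.0,
                                background_sd=0.2, seed=seed)
            curves.append(ephys.tuning_curve(simulate_evoked_dataset(p)))
        g = ephys.group_tuning_curve(curves, ci=0.95)
        assert set(g.columns) >= {"frequency_hz", "mean_threshold_db",
                                  "ci_half_width_db", "n"}
        assert (g["n"] == 5).all()
        assert (g["ci_half_width_db"].dropna() >= 0).all()


class TestIsoLevelProfile:
    def test_constant_has_zero_se(self):
        ds = dataset_from_level_means({lv: 2.0 for lv in LEVELS}, [1.0, 1.0])
        prof = ephys.iso_level_profile(ds, 130)
        assert prof["se"].iloc[0] == 0.0

    def test_two_rep_mean_and_se(self):
        trials = pd.DataFrame({
            "frequency_hz": [95, 95], "level_db": [130, 130],
            "rep": [1, 2], "magnitude_uv": [1.0, 3.0]})
        ds = ephys.EvokedDataset(background=np.array([1.0, 1.0]), trials=trials)
        prof = ephys.iso_level_profile(ds, 130)
        assert prof["mean"].iloc[0] == 2.0
        assert prof["se"].iloc[0] == pytest.approx(1.0)

    def test_off_grid_level_rejected(self):
        ds = dataset_from_level_means({lv: 1.0 for lv in LEVELS}, [1, 1])
        with pytest.raises(ValueError):
            ephys.iso_level_profile(ds, 131)

    def test_saturating_response_non_decreasing(self):
        p = EvokedSimParams(true_threshold=120.0, growth_slope=1.0,
                            background_sd=0.01, seed=2)
        ds = simulate_evoked_dataset(p, frequencies=[95], levels=LEVELS)
        means = [ephys.iso_level_profile(ds, lv)["mean"].iloc[0]
                 for lv in LEVELS]
        assert (np.diff(means) >= -0.05).all()


class TestDetectionRate:
    def _curve(self, thresholds):
        return ephys.TuningCurve(frequencies=np.array([95, 190]),
                                 thresholds=np.array(thresholds, dtype=float),
                                 background_mean=1.0, background_sd=0.2)

    def test_all_defined(self):
        curves = [self._curve([120, 130])] * 4
        rate = ephys.detection_rate(curves)
        assert (rate["detection_rate_pct"] == 100.0).all()

    def test_fractional(self):
        curves = [self._curve([120, np.nan])] * 3 + [self._curve([120, 130])]
        rate = ephys.detection_rate(curves)
        assert rate["detection_rate_pct"].tolist() == [100.0, 25.0]

    def test_order_invariant(self):
        curves = [self._curve([120, np.nan]), self._curve([np.nan, 130]),
                  self._curve([126, 126])]
        a = ephys.detection_rate(curves)
        b = ephys.detection_rate(curves[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_simulated_roll_off_non_increasing(self):
        curves = []
        thr = {95: 120, 190: 125, 285: 130, 380: 140, 475: 150}
        for seed in range(8):
            p = EvokedSimParams(true_threshold=thr, growth_slope=0.6,
                                background_sd=0.3, seed=seed)
            ds = simulate_evoked_dataset(p)
            curves.append(ephys.tuning_curve(ds))
        rate = ephys.detection_rate(curves).set_index("frequency_hz")
        high = rate.loc[475:, "detection_rate_pct"].to_numpy()
        assert (np.diff(high) <= 1e-9).all()


class TestThresholdDifference:
    def _curves(self, offset=0.0, n=4, seed0=0):
        curves = []
        for s in range(n):
            p = EvokedSimParams(true_threshold=125.0 + offset, growth_slope=2.0,
                                background_sd=0.05, saturation_level=60.0,
                                seed=seed0 + s)
            curves.append(ephys.tuning_curve(simulate_evoked_dataset(p)))
        return curves

    def test_identical_groups_zero(self):
        a = self._curves()
        diff = ephys.threshold_difference(a, a)
        assert np.allclose(diff["delta_db"], 0.0)
        assert np.allclose(diff["fold_change"], 1.0)

    def test_six_db_is_twofold(self):
        ca = self._curves(offset=6.0, seed0=10)
        cb = self._curves(offset=0.0, seed0=20)
        diff = ephys.threshold_difference(ca, cb)
        # dB definition: 6.02 dB in amplitude is a factor of 2
        assert 10 ** (6.02 / 20) == pytest.approx(2.0, abs=2e-3)
        assert diff["fold_change"].mean() == pytest.approx(2.0, rel=0.2)

    def test_ten_db_offset_recovered(self):
        ca = self._curves(offset=10.0, seed0=30)
        cb = self._curves(offset=0.0, seed0=40)
        diff = ephys.threshold_difference(ca, cb)
        assert np.abs(diff["delta_db"] - 10.0).max() <= 3.0


class TestThresholdRecoveryRate:
    def test_95_percent_within_one_step(self):
        """200 simulated records: >= 95% of thresholds within one 3 dB step."""
        rng = np.random.default_rng(123)
        hits = total = 0
        for i in range(200):
            truth = float(rng.choice(np.arange(106, 149, 3)))
            p = EvokedSimParams(true_threshold=truth, growth_slope=1.5,
                                background_sd=0.1, background_mean=1.0,
                                saturation_level=60.0,
                                seed=int(rng.integers(2**31)))
            ds = simulate_evoked_dataset(p, frequencies=[95], levels=LEVELS)
            est = ephys.determine_threshold(ds, 95)
            total += 1
            if not np.isnan(est) and abs(est - truth) <= 3.0:
                hits += 1
        assert hits / total >= 0.95
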
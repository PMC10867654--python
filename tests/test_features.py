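import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fatiguecast import features as fx
from fatiguecast.config import RunConfig
from fatiguecast.sleep import SleepPeriod, SleepSchedule


def _ts(s, day=2):
    return pd.Timestamp(f"2021-03-0{day} {s}+01:00")


def _series(values, start, freq="1min"):
    idx = pd.date_range(start, periods=len(values), freq=freq)
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestAggregateStats:
    def test_exact_line(self):
        out = fx.aggregate_stats([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert out["slope"] == pytest.approx(1.0)
        assert out["mean"] == 1.0 and out["min"] == 0.0 and out["max"] == 2.0
        assert out["sd"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_single_value(self):
        out = fx.aggregate_stats([1.0], [4.2])
        assert out["mean"] == out["min"] == out["max"] == 4.2
        assert out["sd"] == 0.0
        assert np.isnan(out["slope"])

    def test_empty(self):
        out = fx.aggregate_stats([], [])
        assert all(np.isnan(v) for v in out.values())

    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(-5, 5)),
                    min_size=3, max_size=30, unique_by=lambda tv: tv[0]))
    def test_slope_matches_closed_form(self, pairs):
        t = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        tc, vc = t - t.mean(), v - v.mean()
        if float(tc @ tc) < 1e-9:
            return
        expect = float(tc @ vc) / float(tc @ tc)
        out = fx.aggregate_stats(t, v)
        assert out["slope"] == pytest.approx(expect, abs=1e-9)


class TestRestWindows:
    def _inputs(self, hr_level=100.0, acc_level=0.01, acc_noise=0.0,
                ibi_artifacts=0, minutes=10):
        start = _ts("10:00")
        rng = np.random.default_rng(0)
        hr = _series(np.full(minutes, hr_level), start)
        acc = _series(acc_level + rng.normal(0, acc_noise, minutes)
                      if acc_noise else np.full(minutes, acc_level), start)
        ibis = np.full(int(minutes * 60 / 0.8), 800.0)
        for i in range(ibi_artifacts):
            ibis[10 + 17 * i] = 2000.0
        t = start + pd.to_timedelta(np.cumsum(ibis) / 1000.0, unit="s")
        ibi = pd.Series(ibis, index=t)
        horizon = (start, start + pd.Timedelta(minutes=minutes))
        return hr, acc, ibi, horizon

    def test_low_hr_quiet_window_qualifies(self):
        """Age 30 puts the rest threshold at 0.55*(220-30) = 104.5 BPM."""
        assert fx.max_rest_hr(30.0) == pytest.approx(104.5)
        hr, acc, ibi, horizon = self._inputs(hr_level=100.0)
        wins = fx.detect_rest_windows(hr, acc, ibi, 30.0, horizon)
        assert len(wins) == 2
        assert all(w.metrics.sdnn == 0.0 for w in wins)

    def test_hr_above_threshold_rejected(self):
        hr, acc, ibi, horizon = self._inputs(hr_level=106.0)
        assert fx.detect_rest_windows(hr, acc, ibi, 30.0, horizon) == []

    def test_continuous_motion_rejected(self):
        hr, acc, ibi, horizon = self._inputs(acc_level=0.5, acc_noise=0.3)
        assert fx.detect_rest_windows(hr, acc, ibi, 30.0, horizon) == []

    def test_artifact_heavy_window_rejected(self):
        # 4 artifacts land in the first 5-min cell -> rejected; the second
        # cell stays clean
        hr, acc, ibi, horizon = self._inputs(ibi_artifacts=4)
        wins = fx.detect_rest_windows(hr, acc, ibi, 30.0, horizon)
        assert len(wins) == 1
        assert wins[0].start >= horizon[0] + pd.Timedelta(minutes=5)

    def test_windows_tile_the_grid(self):
        hr, acc, ibi, horizon = self._inputs(minutes=30)
        wins = fx.detect_rest_windows(hr, acc, ibi, 30.0, horizon)
        assert len(wins) == 6
        for a, b in zip(wins, wins[1:]):
            assert b.start >= a.end


class TestEdaPeaks:
    def _eda(self, n_bumps, amp, fs=1.0, hours=1.0):
        n = int(hours * 3600 * fs)
        idx = pd.date_range(_ts("10:00"), periods=n,
                            freq=pd.Timedelta(seconds=1 / fs))
        values = np.full(n, 2.0)
        kernel = amp * np.exp(-np.arange(0, 30.0, 1 / fs) / 8.0)
        for k in range(n_bumps):
            pos = int((k + 0.5) * n / n_bumps)
            end = min(pos + kernel.size, n)
            values[pos:end] += kernel[:end - pos]
        return pd.Series(values, index=idx)

    def test_flat_signal_has_no_peaks(self):
        eda = self._eda(0, 0.0)
        count, _ = fx.count_eda_peaks(
            eda, (eda.index[0], eda.index[-1] + pd.Timedelta(seconds=1)))
        assert count == 0

    def test_seven_bumps_counted(self):
        eda = self._eda(7, 0.4)
        horizon = (eda.index[0], eda.index[0] + pd.Timedelta(hours=1))
        count, sub = fx.count_eda_peaks(eda, horizon)
        assert count == 7
        assert sub.sum() == 7 and len(sub) == 12

    def test_subthreshold_bumps_ignored(self):
        eda = self._eda(7, 0.02)
        horizon = (eda.index[0], eda.index[0] + pd.Timedelta(hours=1))
        count, _ = fx.count_eda_peaks(eda, horizon)
        assert count == 0


class TestActivity:
    def test_step_sum_inside_horizon(self):
        start = _ts("10:00")
        steps = pd.DataFrame({
            "start": [start, start + pd.Timedelta(minutes=10),
                      start + pd.Timedelta(minutes=20)],
            "end": [start + pd.Timedelta(minutes=10),
                    start + pd.Timedelta(minutes=20),
                    start + pd.Timedelta(minutes=30)],
            "steps": [10, 0, 25]})
        acc = _series(np.ones(120), start)
        out = fx.activity_features(
            acc, steps, (start, start + pd.Timedelta(hours=2)))
        assert out["steps_count"] == pytest.approx(35.0)
        assert out["act_int"] == pytest.approx(2.0, rel=0.02)

    def test_straddling_interval_prorated(self):
        start = _ts("10:00")
        steps = pd.DataFrame({
            "start": [start - pd.Timedelta(minutes=5)],
            "end": [start + pd.Timedelta(minutes=5)],
            "steps": [100]})
        acc = _series(np.ones(60), start)
        out = fx.activity_features(
            acc, steps, (start, start + pd.Timedelta(hours=1)))
        assert out["steps_count"] == pytest.approx(50.0)


class TestRoutine:
    @pytest.fixture
    def schedule(self):
        return SleepSchedule([
            SleepPeriod(_ts("23:00", day=1), _ts("07:00", day=2)),
            SleepPeriod(_ts("23:00", day=2), _ts("07:00", day=3)),
        ])

    def test_interval_arithmetic(self, schedule):
        out = fx.routine_features(_ts("09:30", day=2), schedule)
        assert out["sleep_duration"] == pytest.approx(8.0)
        assert out["time_awake"] == pytest.approx(2.5)
        assert out["time_of_day"] == pytest.approx(9.5)

    def test_wake_at_mean_has_zero_deviation(self, schedule):
        out = fx.routine_features(_ts("09:30", day=2), schedule)
        assert out["wake_dev"] == pytest.approx(0.0, abs=1e-9)
        assert out["bed_dev"] == pytest.approx(0.0, abs=1e-9)

    def test_no_prior_night_masks_sleep_features(self):
        out = fx.routine_features(_ts("09:30"), SleepSchedule([]))
        assert np.isfinite(out["time_of_day"])
        for key in ("time_awake", "sleep_duration", "wake_dev", "bed_dev"):
            assert np.isnan(out[key])


class TestWeather:
    @pytest.fixture
    def weather(self):
        return pd.DataFrame({
            "date": [pd.Timestamp("2021-03-02").date()],
            "temp_mean": [12.0], "temp_min": [7.5], "temp_felt_min": [6.0],
            "dew_mean": [4.0], "humidity_mean": [70.0]})

    def test_day_level_constancy(self, weather):
        a = fx.weather_features(weather, pd.Timestamp("2021-03-02").date())
        b = fx.weather_features(weather, pd.Timestamp("2021-03-02").date())
        assert a == b and a["wea_temp_mean"] == 12.0

    def test_missing_day_masks_all(self, weather):
        out = fx.weather_features(weather, pd.Timestamp("2021-03-05").date())
        assert all(np.isnan(v) for v in out.values())


class TestAssembledTable:
    def test_feature_census_and_tags(self, small_cohort):
        table = small_cohort.features_observed
        assert table.feature_names == fx.feature_names()
        assert set(table.groups.values()) == {"CAR", "EDA", "ACC", "WEA",
                                              "ROUTINE"}

    def test_weather_constant_within_day(self, small_cohort):
        df = small_cohort.features_observed.df
        one = df[df["participant_id"] == df["participant_id"].iloc[0]]
        per_day = one.groupby(one["rating_time"].dt.date)["wea_temp_mean"]
        assert (per_day.nunique() <= 1).all()
        assert (one["wea_temp_min"] <= one["wea_temp_mean"]).all()

    def test_horizon_nesting_of_extrema(self, small_cohort):
        """For ratings > 6 h after waking the 1h/3h/6h windows nest, so
        minima are non-increasing and maxima non-decreasing with window
        length."""
        table = small_cohort.features_observed
        df = table.df
        late = df[df["time_awake"] > 6.5]
        assert len(late) > 5
        for sig in ("hr", "sdnn"):
            sub = late[[f"{sig}_{hz}_{s}" for hz in ("1h", "3h", "6h")
                        for s in ("min", "max")]].dropna()
            assert (sub[f"{sig}_1h_min"] >= sub[f"{sig}_3h_min"] - 1e-9).all()
            assert (sub[f"{sig}_3h_min"] >= sub[f"{sig}_6h_min"] - 1e-9).all()
            assert (sub[f"{sig}_1h_max"] <= sub[f"{sig}_3h_max"] + 1e-9).all()
            assert (sub[f"{sig}_3h_max"] <= sub[f"{sig}_6h_max"] + 1e-9).all()

    def test_extraction_is_deterministic(self, small_cohort, fast_config):
        import warnings

        from fatiguecast.sleep import estimate_sleep_wake
        pid = small_cohort.participants["id"].iloc[0]
        bundle = small_cohort.bundles[pid]
        age = small_cohort.ages[pid]
        schedule = estimate_sleep_wake(bundle.acc, bundle.hr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = fx.assemble_features(bundle, small_cohort.ratings[pid],
                                      schedule, small_cohort.weather, age)
            t2 = fx.assemble_features(bundle, small_cohort.ratings[pid],
                                      schedule, small_cohort.weather, age)
        pd.testing.assert_frame_equal(t1.df, t2.df)
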
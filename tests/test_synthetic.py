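import warnings

import numpy as np
import pandas as pd
import pytest

from fatiguecast import hrv
from fatiguecast.config import ParameterError
from fatiguecast.synthetic import (CohortSpec, Effect, TruthModel,
                                   default_truth, generate_cohort,
                                   generate_ibi_series, generate_ratings,
                                   inject_missingness)


class TestIbiGenerator:
    def test_calibration_against_extractor(self):
        """A 10-min realization lands within 15% of the SDNN/SD1 targets
        when measured by the package's own Poincaré extractor."""
        series = generate_ibi_series(
            {"mean_ibi_ms": 850, "sdnn_ms": 50, "sd1_ms": 30},
            duration_s=600, seed=5)
        m = hrv.poincare_metrics(series.to_numpy())
        assert 42.5 <= m.sdnn <= 57.5
        assert 25.5 <= m.sd1 <= 34.5

    def test_zero_variance_target(self):
        series = generate_ibi_series(
            {"mean_ibi_ms": 850, "sdnn_ms": 0, "sd1_ms": 0},
            duration_s=60, seed=1)
        assert np.all(series.to_numpy() == 850.0)

    def test_zero_duration(self):
        series = generate_ibi_series(
            {"mean_ibi_ms": 850, "sdnn_ms": 50, "sd1_ms": 30},
            duration_s=0, seed=1)
        assert len(series) == 0

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ParameterError, match="infeasible"):
            generate_ibi_series(
                {"mean_ibi_ms": 850, "sdnn_ms": 30, "sd1_ms": 50},
                duration_s=60, seed=1)

    def test_deterministic(self):
        a = generate_ibi_series({"mean_ibi_ms": 900, "sdnn_ms": 40,
                                 "sd1_ms": 25}, 120, seed=9)
        b = generate_ibi_series({"mean_ibi_ms": 900, "sdnn_ms": 40,
                                 "sd1_ms": 25}, 120, seed=9)
        assert a.equals(b)

    def test_all_positive(self):
        series = generate_ibi_series(
            {"mean_ibi_ms": 600, "sdnn_ms": 120, "sd1_ms": 100},
            duration_s=600, seed=2)
        assert (series.to_numpy() > 0).all()


class TestTruthModel:
    def test_unknown_feature_rejected(self):
        truth = TruthModel(effects={"CO": [Effect("not_a_feature", "rise",
                                                  0.3)]})
        with pytest.raises(ParameterError, match="not_a_feature"):
            truth.validate()

    def test_default_truth_validates(self):
        default_truth().validate()

    def test_effect_shapes_match_labels_on_grid(self):
        """Every declared effect shape matches the sign pattern of its
        first differences on a dense grid."""
        grid = np.linspace(-2.5, 2.5, 201)
        for effects in default_truth().effects.values():
            for e in effects:
                v = e(grid)
                d = np.diff(v)
                assert np.all(np.abs(v) <= abs(e.amplitude) + 1e-9)
                if e.shape == "rise":
                    assert np.all(d > 0)
                elif e.shape == "fall":
                    assert np.all(d < 0)
                elif e.shape == "arch":
                    i = int(np.argmax(v))
                    assert 0 < i < len(v) - 1
                    assert np.all(d[:i] > 0) and np.all(d[i:] < 0)
                elif e.shape == "dip":
                    i = int(np.argmin(v))
                    assert np.all(d[:i] < 0) and np.all(d[i:] > 0)

    def test_truth_record_tabulates_effects(self):
        rec = default_truth().to_record()
        assert set(rec["effects"]) == {"CO", "MS_I", "MS_II"}
        assert rec["noise_sd"] == 0.8
        first = rec["effects"]["CO"][0]
        assert len(first["values"]) == len(rec["grid"])


class TestGenerateRatings:
    def _norm_table(self, n=120, seed=0):
        from helpers import feature_table
        table = feature_table(3, n // 3, {}, noise_sd=1.0, seed=seed,
                              n_noise_features=1)
        rng = np.random.default_rng(seed + 1)
        table.df["f_noise_0"] = rng.normal(0, 1, n)
        return table

    def _participants(self):
        return pd.DataFrame({
            "id": ["P00", "P01", "P02"], "group": "CO",
            "mean_vas": [5.0, 5.0, 5.0], "sd_vas": [1.0, 1.0, 1.0]})

    def test_noiseless_identity_effect(self):
        """With zero noise and one linear effect the rating is a rounded
        affine image of that feature: correlation 1 up to the 0.1-point
        quantization of the VAS scale."""
        table = self._norm_table()
        truth = TruthModel(effects={"CO": [Effect("f_noise_0", "linear",
                                                  1.0)]}, noise_sd=0.0)
        out = generate_ratings(table, truth, seed=3,
                               participants=self._participants())
        x = table.df["f_noise_0"].to_numpy()
        r = np.corrcoef(x, out["vas"].to_numpy())[0, 1]
        assert r > 0.999

    def test_vas_bounds_and_quantization(self):
        table = self._norm_table()
        truth = TruthModel(effects={"CO": [Effect("f_noise_0", "linear",
                                                  5.0)]}, noise_sd=0.5)
        out = generate_ratings(table, truth, seed=4,
                               participants=self._participants())
        vas = out["vas"].to_numpy()
        assert vas.min() >= 1.0 and vas.max() <= 10.0
        np.testing.assert_allclose(vas, np.round(vas, 1))


class TestCohort:
    def test_group_sizes_and_metadata(self, small_cohort):
        parts = small_cohort.participants
        assert parts["group"].value_counts().to_dict() == {
            "CO": 2, "MS_I": 2, "MS_II": 2}
        ms2 = parts[parts["group"] == "MS_II"]
        assert (ms2["compass"] > 17).all()
        ms1 = parts[parts["group"] == "MS_I"]
        assert (ms1["compass"] <= 17).all()
        assert parts["age"].between(18, 65).all()
        assert parts.loc[parts["group"] != "CO", "fsmc"].notna().all()

    def test_rating_counts_near_poisson_expectation(self, small_cohort):
        counts = [len(r) for r in small_cohort.ratings.values()]
        expected = small_cohort.spec.days * small_cohort.spec.ratings_per_day
        total_sd = np.sqrt(expected * len(counts))
        assert abs(sum(counts) - expected * len(counts)) < 4 * total_sd

    def test_ratings_fall_in_wake_hours(self, small_cohort):
        for pid, ratings in small_cohort.ratings.items():
            schedule = small_cohort.schedules_true[pid]
            for t in ratings["timestamp"]:
                assert schedule.covering(t) is None

    def test_missingness_rate_and_cardiac_dominance(self, small_cohort):
        table = small_cohort.features_observed
        frac = table.incomplete_rows().mean()
        assert 0.20 <= frac <= 0.30
        car = [f for f in table.feature_names
               if table.groups[f] == "CAR"]
        miss = ~table.mask[table.feature_names].to_numpy()
        idx = [table.feature_names.index(f) for f in car]
        inc_rows = np.nonzero(table.incomplete_rows())[0]
        frac_cardiac = miss[inc_rows][:, idx].any(axis=1).mean()
        assert frac_cardiac >= 0.5

    def test_zero_missing_rate_gives_complete_vectors(self, clean_cohort):
        table = clean_cohort.features_observed
        assert table.incomplete_rows().mean() < 0.05

    def test_time_of_day_truth_creates_daily_trend(self, clean_cohort):
        """A rise-only time-of-day effect shows up as increasing mean
        normalized ratings across morning/noon/evening bins."""
        from fatiguecast import preprocess
        norm, _ = preprocess.normalize_per_participant(
            clean_cohort.features_observed)
        df = norm.df
        hours = df["time_of_day"]
        # undo normalization for binning: use raw rating hour
        raw_hour = pd.to_datetime(df["rating_time"]).dt.hour
        bins = pd.cut(raw_hour, [0, 12, 17, 24],
                      labels=["morning", "noon", "evening"])
        means = df.groupby(bins, observed=True)["vas_norm"].mean()
        assert means["morning"] < means["noon"] < means["evening"]
        del hours

    def test_determinism_of_generation(self):
        spec = CohortSpec(n_co=1, n_ms1=1, n_ms2=0, days=2, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_cohort(spec)
            b = generate_cohort(spec)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.all_ratings(), b.all_ratings())
        pd.testing.assert_frame_equal(a.features_observed.df,
                                      b.features_observed.df)

    def test_zero_ratings_per_day(self):
        spec = CohortSpec(n_co=1, n_ms1=0, n_ms2=0, days=1,
                          ratings_per_day=0.0, missing_rate=0.0, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = generate_cohort(spec)
        assert len(cohort.all_ratings()) == 0
        assert len(cohort.features_observed) == 0


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, clean_cohort):
        pid = clean_cohort.participants["id"].iloc[0]
        bundle = clean_cohort.bundles[pid]
        times = clean_cohort.ratings[pid]["timestamp"]
        out, chosen = inject_missingness(bundle, times, 0.0, seed=2)
        assert chosen == []
        assert out.acc.equals(bundle.acc)

    def test_bursts_cover_pre_rating_hour(self, clean_cohort):
        pid = clean_cohort.participants["id"].iloc[0]
        bundle = clean_cohort.bundles[pid]
        times = list(clean_cohort.ratings[pid]["timestamp"])
        out, chosen = inject_missingness(bundle, times, 0.3, seed=3)
        assert len(chosen) == round(0.3 * len(times))
        changed = ~np.isclose(out.acc.to_numpy(), bundle.acc.to_numpy()) \
            | (np.isnan(out.eda.to_numpy()) & ~np.isnan(bundle.eda.to_numpy()))
        assert changed.any()
        # every changed sample lies within 70 min before a chosen rating
        changed_times = out.acc.index[changed]
        for t in changed_times:
            assert any(
                times[i] - pd.Timedelta(minutes=70) <= t < times[i]
                for i in chosen)
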